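"""Isotemporal substitution: change matrices for pairwise reallocations.

A reallocation moves a fixed number of minutes (default 10) from a
donor behaviour to a receiver behaviour at a reference composition
(the group's geometric-mean composition).  The predicted change in an
outcome is the fitted ILR coefficient vector applied to the difference
of ILR coordinates; covariate terms cancel exactly.  Changes are
expressed as a percentage around the sample mean of the outcome and
flagged against the smallest worthwhile change (SWC), defined as
0.2 x group standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import Composition, ilr_transform
from .models import OutcomeModelFit


class InfeasibleReallocation(ValueError):
    """The donor behaviour has too few minutes to give up."""


@dataclass(frozen=True)
class ReallocationSpec:
    donor: str
    receiver: str
    delta: float = 10.0

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError("donor and receiver must differ")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


@dataclass(frozen=True)
class SwcThreshold:
    """Smallest worthwhile change: 0.2 x group SD, in outcome units."""

    outcome: str
    group: str
    value: float
    as_percent_of_mean: float


@dataclass(frozen=True)
class PredictedChange:
    percent: float         # % change around the sample mean
    absolute: float        # same change in outcome units
    delta_model: float     # change on the modelling (possibly log) scale


def reallocate(reference: Composition, spec: ReallocationSpec) -> Composition:
    """Move ``delta`` minutes from donor to receiver; other parts fixed."""
    donor_min = reference[spec.donor]
    if donor_min - spec.delta <= 0:
        raise InfeasibleReallocation(
            f"{spec.donor} has {donor_min:.1f} min; cannot remove "
            f"{spec.delta:.1f}")
    values = reference.values.copy()
    values[reference.parts.index(spec.donor)] -= spec.delta
    values[reference.parts.index(spec.receiver)] += spec.delta
    return Composition(values, reference.parts, reference.total)


def predict_change(fit: OutcomeModelFit, reference: Composition,
                   spec: ReallocationSpec,
                   outcome_mean: float | None = None,
                   exact_percent: bool = True) -> PredictedChange:
    """Predicted outcome change for one reallocation.

    ``delta_model = beta' (ilr(reallocated) - ilr(reference))``; for log
    outcomes the percent change is ``(exp(delta) - 1) * 100`` (or
    ``delta * 100`` when ``exact_percent`` is off), for identity
    outcomes ``delta / mean * 100``.
    """
    if tuple(reference.parts) != tuple(fit.basis.part_order):
        raise ValueError("fit and reference disagree on part order")
    mean = fit.outcome_mean if outcome_mean is None else float(outcome_mean)
    moved = reallocate(reference, spec)
    dz = ilr_transform(moved, fit.basis) - ilr_transform(reference, fit.basis)
    dy = float(fit.ilr_coef @ dz)
    if fit.outcome.transform == "log":
        frac = np.expm1(dy) if exact_percent else dy
        return PredictedChange(100.0 * frac, mean * frac, dy)
    return PredictedChange(100.0 * dy / mean, dy, dy)


def compute_swc(values: np.ndarray, outcome: str, group: str = "all"
                ) -> SwcThreshold:
    """SWC from raw outcome values of one group (n-1 SD)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("SWC needs at least two observations")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("zero SD: SWC undefined")
    mean = float(np.mean(vals))
    return SwcThreshold(outcome, group, 0.2 * sd, 100.0 * 0.2 * sd / abs(mean))


def swc_by_sex(records: pd.DataFrame, outcome_col: str) -> dict[str, SwcThreshold]:
    return {sex: compute_swc(grp[outcome_col].to_numpy(dtype=float),
                             outcome_col, sex)
            for sex, grp in records.groupby("sex", observed=True)}


@dataclass(frozen=True)
class ChangeMatrix:
    """Predicted % changes for all ordered 10-min reallocations.

    Rows are receivers, columns donors (a cell is the effect of moving
    time *from* the column behaviour *to* the row behaviour).  Cells
    whose donor cannot spare ``delta`` minutes are NaN; the diagonal is
    NaN.  ``flags`` marks absolute changes exceeding the SWC.
    ``extreme_percent_warning`` is set when any |percent| exceeds 100 --
    the near-zero-mean pathology (e.g. BMI z-scores averaging ~0) where
    percent-of-mean is numerically valid but practically meaningless;
    consult ``absolute`` in outcome units instead.
    """

    outcome: str
    group: str
    percent: pd.DataFrame
    absolute: pd.DataFrame
    flags: pd.DataFrame
    swc: SwcThreshold
    reference: Composition
    delta: float
    extreme_percent_warning: bool


def change_matrix(fit: OutcomeModelFit, reference: Composition,
                  swc: SwcThreshold, delta: float = 10.0,
                  outcome_mean: float | None = None,
                  group: str = "all",
                  exact_percent: bool = True) -> ChangeMatrix:
    """Evaluate all ordered donor/receiver pairs at the reference."""
    parts = list(reference.parts)
    pct = pd.DataFrame(np.nan, index=parts, columns=parts)
    absu = pd.DataFrame(np.nan, index=parts, columns=parts)
    for donor in parts:
        for receiver in parts:
            if donor == receiver:
                continue
            spec = ReallocationSpec(donor, receiver, delta)
            try:
                ch = predict_change(fit, reference, spec, outcome_mean,
                                    exact_percent)
            except InfeasibleReallocation:
                continue  # reported as missing, never fabricated
            pct.loc[receiver, donor] = ch.percent
            absu.loc[receiver, donor] = ch.absolute
    flags = absu.abs() > swc.value
    flags[absu.isna()] = False
    warn = bool(np.nanmax(np.abs(pct.to_numpy()), initial=0.0) > 100.0)
    return ChangeMatrix(fit.outcome.name, group, pct, absu, flags, swc,
                        reference, delta, warn)


def reallocation_volume_percent(delta: float, mean_minutes: float) -> float:
    """A ``delta``-minute reallocation as a percent of mean daily volume."""
    if mean_minutes <= 0:
        raise ValueError("mean minutes must be positive")
    return 100.0 * delta / mean_minutes
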