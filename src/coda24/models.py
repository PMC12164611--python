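"""Compositional linear models of outcomes on ILR coordinates.

The central estimator regresses a (possibly log-transformed)
cardiometabolic outcome on the D-1 isometric log-ratio coordinates of
the movement composition plus dummy-coded covariates.  The joint F test
of the ILR block against the covariate-only model gives the model p
value; the increment in R-squared over the covariate-only model is the
share of variance attributable to the composition.  Refitting with each
behaviour in the pivot position yields the one-coefficient-per-behaviour
summary: the first pivot coordinate contrasts that behaviour against the
geometric mean of the remaining four, so its coefficient is "the"
association of that behaviour adjusted for the rest of the composition.

Model p, R-squared, fitted values and residuals are invariant to the
choice of ILR basis (orthogonal reparameterisation); only the
coefficient labelling rotates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .composition import (DAY_MINUTES, PARTS, IlrBasis, ilr_inverse,
                          ilr_transform, pivot_basis)

#: Records-table columns holding part minutes, in canonical part order.
PART_COLUMNS: tuple[str, ...] = ("sed", "lpa", "mpa", "vpa", "sleep")

#: Default covariate set: age in years plus dummy-coded sex, ethnicity
#: and month of monitoring.
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "ethnicity", "month")

#: Reference levels for dummy coding.
REFERENCE_LEVELS: dict[str, object] = {"sex": "male", "ethnicity": "White",
                                       "month": 1}


@dataclass(frozen=True)
class OutcomeSpec:
    """One cardiometabolic outcome and how it enters the model."""

    name: str
    transform: str = "identity"  # "identity" or "log" (natural log)
    units: str = ""
    column: str | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.column is None:
            object.__setattr__(self, "column", self.name)

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.transform == "log":
            if np.any(y <= 0):
                raise ValueError(f"{self.name}: log transform needs positive values")
            return np.log(y)
        return np.asarray(y, dtype=float)


#: The outcome panel, with the log/identity choice used in the analysis.
DEFAULT_OUTCOMES: tuple[OutcomeSpec, ...] = (
    OutcomeSpec("bmi", "log", "kg/m^2"),
    OutcomeSpec("bmi_z", "identity", "z-score"),
    OutcomeSpec("glucose", "log", "mmol/L"),
    OutcomeSpec("insulin", "log", "pmol/L"),
    OutcomeSpec("hdl", "log", "mmol/L"),
    OutcomeSpec("ldl", "log", "mmol/L"),
    OutcomeSpec("triglycerides", "log", "mmol/L"),
    OutcomeSpec("sbp", "identity", "mmHg"),
    OutcomeSpec("dbp", "identity", "mmHg"),
    OutcomeSpec("waist", "log", "cm"),
)


class IlrTransformer(TransformerMixin, BaseEstimator):
    """Map rows of part minutes to ILR coordinates (sklearn transformer).

    Parameters
    ----------
    parts : sequence of str
        Part labels in canonical order.
    pivot_first : str, optional
        Lead part of the pivot basis; defaults to the first canonical part.
    total : float
        Closure constant used by :meth:`inverse_transform`.
    """

    def __init__(self, parts: Sequence[str] = PARTS,
                 pivot_first: str | None = None,
                 total: float = DAY_MINUTES):
        self.parts = parts
        self.pivot_first = pivot_first
        self.total = total

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        parts = tuple(self.parts)
        if X.ndim != 2 or X.shape[1] != len(parts):
            raise ValueError(f"X must have {len(parts)} part columns")
        first = self.pivot_first if self.pivot_first is not None else parts[0]
        self.basis_ = pivot_basis(first, parts=parts)
        self.n_features_in_ = len(parts)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "basis_")
        X = np.asarray(X, dtype=float)
        return ilr_transform(X, self.basis_)

    def inverse_transform(self, Z) -> np.ndarray:
        check_is_fitted(self, "basis_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return ilr_inverse(Z, self.basis_, total=self.total)


def _dummy_code(records: pd.DataFrame, covariates: Sequence[str],
                references: Mapping[str, object],
                levels: Mapping[str, tuple] | None = None
                ) -> tuple[pd.DataFrame, dict[str, tuple]]:
    """Numeric + dummy-coded covariate design (no intercept column).

    Categorical covariates are any non-numeric columns (plus month); the
    configured reference level (or the first observed) is dropped.
    Covariates with a single observed level are omitted entirely, so
    sex-stratified fits do not carry a degenerate sex column.  Passing
    the ``levels`` mapping returned by a previous call reproduces the
    fitted column set on new data (unseen levels fold into the
    reference).
    """
    cols: dict[str, np.ndarray] = {}
    levels_used: dict[str, tuple] = {}
    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"covariate column {cov!r} missing from records")
        col = records[cov]
        categorical = (levels[cov][0] is not None if levels is not None
                       and cov in levels
                       else not pd.api.types.is_numeric_dtype(col)
                       or cov == "month")
        if not categorical:
            cols[cov] = col.to_numpy(dtype=float)
            levels_used[cov] = (None, None)
            continue
        if levels is not None:
            if cov not in levels:
                continue
            lev_list, ref = levels[cov]
            if lev_list is None:
                continue
        else:
            lev_list = sorted(col.astype(str).unique())
            if len(lev_list) < 2:
                continue
            ref = str(references.get(cov, lev_list[0]))
            if ref not in lev_list:
                ref = lev_list[0]
        levels_used[cov] = (tuple(lev_list), ref)
        for lev in lev_list:
            if lev == ref:
                continue
            cols[f"{cov}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
    return pd.DataFrame(cols, index=records.index), levels_used


def _check_full_rank(design: pd.DataFrame) -> None:
    """Raise naming the first column that is collinear with its predecessors."""
    X = design.to_numpy(dtype=float)
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    bad = np.where(diag / scale < 1e-8)[0]
    if bad.size:
        raise ValueError(f"design is rank deficient: column "
                         f"{design.columns[bad[0]]!r} is collinear")


@dataclass(frozen=True)
class PivotCoefficient:
    """First-pivot-coordinate coefficient of one behaviour."""

    behaviour: str
    coefficient: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class OutcomeModelFit:
    """Fitted compositional model of one outcome; one report row."""

    outcome: OutcomeSpec
    n: int
    model_f: float
    model_p: float
    r_squared: float            # per the configured mode
    r_squared_total: float
    r_squared_increment: float
    behaviours: dict[str, PivotCoefficient]
    covariate_coefficients: dict[str, float]
    residual_sd: float
    ilr_coef: np.ndarray = field(repr=False)   # canonical pivot basis
    clr_coef: np.ndarray = field(repr=False)   # zero-sum CLR projection
    basis: IlrBasis = field(repr=False)
    outcome_mean: float = float("nan")         # raw-scale sample mean


class CompositionalRegression(RegressorMixin, BaseEstimator):
    """OLS of one outcome on ILR coordinates plus covariates.

    ``fit`` expects a DataFrame with the five part-minute columns
    (``part_columns``) and the covariate columns; rows must be complete
    cases.  Predictions are on the modelling scale (log scale for log
    outcomes).

    Parameters
    ----------
    outcome_transform : {"identity", "log"}
        Transform applied to y before fitting.
    covariates : sequence of str
        Covariate columns; non-numeric ones are dummy coded against
        ``REFERENCE_LEVELS``.
    r_squared_mode : {"increment", "total"}
        Whether ``r_squared_`` reports the compositional increment over
        the covariate-only model (default) or the full-model R-squared.
    fit_pivots : bool
        Refit under all D pivot rotations to populate per-behaviour
        coefficients (skippable for speed in simulations).
    """

    def __init__(self, outcome_transform: str = "identity",
                 parts: Sequence[str] = PARTS,
                 part_columns: Sequence[str] = PART_COLUMNS,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 references: Mapping[str, object] = REFERENCE_LEVELS,
                 r_squared_mode: str = "increment",
                 fit_pivots: bool = True):
        self.outcome_transform = outcome_transform
        self.parts = parts
        self.part_columns = part_columns
        self.covariates = covariates
        self.references = references
        self.r_squared_mode = r_squared_mode
        self.fit_pivots = fit_pivots

    # -- internals ---------------------------------------------------------

    def _design(self, X: pd.DataFrame, basis: IlrBasis,
                levels: Mapping[str, tuple] | None = None) -> pd.DataFrame:
        parts = tuple(self.parts)
        missing = [c for c in self.part_columns if c not in X.columns]
        if missing:
            raise KeyError(f"part columns missing from records: {missing}")
        mins = X.loc[:, list(self.part_columns)].to_numpy(dtype=float)
        if np.any(mins <= 0):
            raise ValueError("part minutes must be strictly positive "
                             "(zero-replace upstream)")
        Z = ilr_transform(mins, basis)
        design = pd.DataFrame(
            {f"ilr{i + 1}": Z[:, i] for i in range(len(parts) - 1)},
            index=X.index)
        cov, self._cov_levels_last = _dummy_code(
            X, self.covariates, dict(self.references), levels)
        design = pd.concat([design, cov], axis=1)
        design.insert(0, "const", 1.0)
        return design

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        if self.r_squared_mode not in ("increment", "total"):
            raise ValueError("r_squared_mode must be 'increment' or 'total'")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of records")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(X):
            raise ValueError("X and y lengths differ")
        if np.isnan(y).any() or X[list(self.part_columns)].isna().any().any():
            raise ValueError("fit requires complete cases; drop NaNs upstream")

        parts = tuple(self.parts)
        spec = OutcomeSpec("y", self.outcome_transform)
        self.outcome_mean_ = float(np.mean(y))
        y_model = spec.apply(y)

        basis = pivot_basis(parts[0], parts=parts)
        design = self._design(X, basis)
        k_ilr = len(parts) - 1
        n, p = design.shape
        if n <= p:
            raise ValueError(f"n={n} too small for {p} parameters")
        _check_full_rank(design)

        full = sm.OLS(y_model, design).fit()
        reduced = sm.OLS(y_model, design.drop(
            columns=[f"ilr{i + 1}" for i in range(k_ilr)])).fit()

        # Joint F test of the ILR block against the covariate-only model.
        rss_f, rss_r = full.ssr, reduced.ssr
        df_f = full.df_resid
        f_stat = ((rss_r - rss_f) / k_ilr) / (rss_f / df_f)
        model_p = float(sps.f.sf(f_stat, k_ilr, df_f))

        self.basis_ = basis
        self.results_ = full
        self.n_ = int(n)
        self.model_f_ = float(f_stat)
        self.model_p_ = model_p
        self.r_squared_total_ = float(full.rsquared)
        self.r_squared_increment_ = float(full.rsquared - reduced.rsquared)
        self.r_squared_ = (self.r_squared_increment_
                           if self.r_squared_mode == "increment"
                           else self.r_squared_total_)
        self.residual_sd_ = float(np.sqrt(full.scale))
        ilr_names = [f"ilr{i + 1}" for i in range(k_ilr)]
        self.coef_ = full.params[ilr_names].to_numpy()
        self.clr_coef_ = basis.contrast_matrix.T @ self.coef_
        self.covariate_coef_ = {name: float(v)
                                for name, v in full.params.items()
                                if name not in ilr_names}
        self.feature_names_in_ = np.asarray(design.columns, dtype=object)
        self.covariate_levels_ = dict(self._cov_levels_last)

        self.pivot_coefficients_: dict[str, PivotCoefficient] = {}
        if self.fit_pivots:
            for b in parts:
                b_basis = pivot_basis(b, parts=parts)
                b_design = self._design(X, b_basis, self.covariate_levels_)
                res = sm.OLS(y_model, b_design).fit()
                ci = res.conf_int().loc["ilr1"]
                self.pivot_coefficients_[b] = PivotCoefficient(
                    b, float(res.params["ilr1"]), float(res.pvalues["ilr1"]),
                    float(ci[0]), float(ci[1]))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor on the modelling scale (log scale if log outcome)."""
        check_is_fitted(self, "results_")
        design = self._design(X, self.basis_, self.covariate_levels_)
        design = design.loc[:, self.feature_names_in_]
        return np.asarray(self.results_.predict(design))

    def to_fit(self, outcome: OutcomeSpec) -> OutcomeModelFit:
        """Package the fitted state as an :class:`OutcomeModelFit`."""
        check_is_fitted(self, "results_")
        return OutcomeModelFit(
            outcome=outcome, n=self.n_, model_f=self.model_f_,
            model_p=self.model_p_, r_squared=self.r_squared_,
            r_squared_total=self.r_squared_total_,
            r_squared_increment=self.r_squared_increment_,
            behaviours=dict(self.pivot_coefficients_),
            covariate_coefficients=dict(self.covariate_coef_),
            residual_sd=self.residual_sd_, ilr_coef=self.coef_.copy(),
            clr_coef=self.clr_coef_.copy(), basis=self.basis_,
            outcome_mean=self.outcome_mean_)


def fit_compositional_model(records: pd.DataFrame, outcome: OutcomeSpec,
                            covariates: Sequence[str] = DEFAULT_COVARIATES,
                            r_squared_mode: str = "increment",
                            fit_pivots: bool = True) -> OutcomeModelFit:
    """Fit the compositional model for one outcome (listwise deletion).

    Rows missing the outcome or any covariate are dropped, so each
    outcome's model uses exactly the participants who have that outcome.
    """
    col = outcome.column
    if col not in records.columns:
        raise KeyError(f"outcome column {col!r} missing from records")
    needed = [col, *covariates, *PART_COLUMNS]
    data = records.dropna(subset=[c for c in needed if c in records.columns])
    est = CompositionalRegression(
        outcome_transform=outcome.transform, covariates=covariates,
        r_squared_mode=r_squared_mode, fit_pivots=fit_pivots)
    est.fit(data, data[col].to_numpy(dtype=float))
    return est.to_fit(outcome)


def summarize_models(fits: Sequence[OutcomeModelFit],
                     parts: Sequence[str] = PARTS) -> tuple[pd.DataFrame,
                                                            tuple[float, float]]:
    """One row per outcome (model p, R^2, per-behaviour coefficient and p),
    plus the headline (min, max) variance-explained range across outcomes."""
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        row: dict[str, object] = {"outcome": f.outcome.name,
                                  "transform": f.outcome.transform,
                                  "n": f.n, "model_p": f.model_p,
                                  "r_squared": f.r_squared}
        for b in parts:
            pc = f.behaviours.get(b)
            row[f"Y_{b}"] = pc.coefficient if pc else np.nan
            row[f"p_{b}"] = pc.p_value if pc else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    r2 = [f.r_squared for f in fits]
    return table, (float(min(r2)), float(max(r2)))
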