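"""Logistic-normal synthetic cohorts with ground-truth bookkeeping.

Participant compositions are drawn with Gaussian ILR coordinates around
a sex-specific centre (defaults: the cohort geometric-mean compositions
of the movement study this pipeline reproduces), mapped back to the
simplex and closed to 1440 min.  Outcomes are exactly linear in the ILR
coordinates of the *assembled* composition (the one the ingest step
will reconstruct from the generated days) plus covariate effects and
Gaussian noise, so the regression stage is correctly specified and
parameter-recovery tests are sharp.  Every planted quantity -- ILR
coefficients, noise SDs, invalid days, missing outcomes -- is recorded
in a :class:`GroundTruth` object that the pipeline under test never
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (DAY_MINUTES, PARTS, Composition,
                          geometric_mean_composition, ilr_inverse,
                          ilr_transform, pivot_basis)
from .ingest import FilterConfig, build_cohort
from .models import (PART_COLUMNS, OutcomeSpec, fit_compositional_model)

SEXES = ("male", "female")

#: Sex-specific compositional centres, minutes (closed to 1440):
#: SED, LPA, MPA, VPA, Sleep.
DEFAULT_MEAN_COMPOSITION: dict[str, tuple[float, ...]] = {
    "male": (342.1, 350.7, 40.5, 14.0, 692.7),
    "female": (365.8, 348.5, 30.2, 11.5, 681.1),
}

#: Per-part log-scale SDs used to build the default ILR covariance:
#: relative day-to-day spread is largest for VPA, smallest for sleep.
DEFAULT_PART_LOG_SD: tuple[float, ...] = (0.25, 0.20, 0.45, 0.70, 0.09)

DEFAULT_ETHNICITY_PROBS: dict[str, float] = {
    "White": 0.851, "Black": 0.003, "Asian": 0.008, "NotReported": 0.138}

#: Valid-day-count distribution over 3..7 days (mean 5.8, SD 1.2).
DEFAULT_N_DAYS = ((3, 4, 5, 6, 7), (0.05, 0.10, 0.20, 0.30, 0.35))

_CANON = pivot_basis(PARTS[0])


def default_ilr_covariance(part_log_sd: Sequence[float] = DEFAULT_PART_LOG_SD
                           ) -> np.ndarray:
    """ILR covariance of independent per-part log-normal spread.

    With per-part log variances s^2, the CLR covariance is the centred
    diag(s^2); projecting through the canonical contrast matrix V gives
    Sigma_ilr = V diag(s^2) V'.
    """
    V = _CANON.contrast_matrix
    return V @ np.diag(np.square(part_log_sd)) @ V.T


def pivot_coefficients_from_clr(clr_coef: np.ndarray) -> dict[str, float]:
    """First-pivot-coordinate coefficient per behaviour implied by a
    zero-sum CLR coefficient vector (equals sqrt(D/(D-1)) * clr_b)."""
    out = {}
    for b in PARTS:
        v1 = pivot_basis(b).contrast_matrix[0]
        out[b] = float(v1 @ np.asarray(clr_coef, float))
    return out


@dataclass(frozen=True)
class OutcomePlant:
    """Planted generative model for one outcome.

    ``clr_coef`` is the zero-sum CLR coefficient vector (model scale per
    unit CLR); ``mean_level`` the intercept on the model scale (log
    scale for log outcomes).  ``noise_sd`` may be given directly or
    derived from ``target_r2`` (the population compositional-increment
    R-squared) at generation time.
    """

    spec: OutcomeSpec
    clr_coef: tuple[float, ...]
    mean_level: float
    age_coef: float = 0.0
    female_coef: float = 0.0
    noise_sd: float | None = None
    target_r2: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.clr_coef, float)
        if abs(c.sum()) > 1e-8:
            raise ValueError(f"{self.spec.name}: clr_coef must sum to zero")
        if self.noise_sd is None and self.target_r2 is None:
            raise ValueError(f"{self.spec.name}: need noise_sd or target_r2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _scaled_plant(name: str, transform: str, pattern: Sequence[float],
                  mean_level: float, sd_model: float, target_r2: float,
                  missing_rate: float, age_coef: float = 0.0,
                  female_coef: float = 0.0) -> OutcomePlant:
    """Build a plant from a per-behaviour coefficient *pattern*.

    The pattern (signs and relative sizes, one entry per behaviour) is
    projected onto the zero-sum CLR space and rescaled so that, under
    the default ILR covariance, the compositional signal accounts for
    ``target_r2`` of a total model-scale variance ``sd_model**2``.
    Published per-behaviour coefficients fix the direction; the scale is
    set self-consistently because coefficient units and variance shares
    cannot both be taken at face value without the source data.
    """
    c = np.asarray(pattern, float)
    c = c - c.mean()
    b0 = _CANON.contrast_matrix @ c
    var0 = float(b0 @ default_ilr_covariance() @ b0)
    k = np.sqrt(target_r2 * sd_model ** 2 / var0)
    return OutcomePlant(OutcomeSpec(name, transform), tuple(k * c),
                        mean_level, age_coef, female_coef, None, target_r2,
                        missing_rate)


def default_outcome_plants() -> tuple[OutcomePlant, ...]:
    """Ten-outcome panel emulating the cohort's published structure:
    coefficient sign patterns, variance-explained shares, outcome means
    and SDs, and per-outcome availability rates."""
    t4 = [
        # name, transform, (SED, LPA, MPA, VPA, Sleep) pattern,
        # mean level (model scale), model-scale SD, increment R2, missing
        ("bmi", "log", (0.004, 0.004, 0.001, -0.005, -0.004),
         np.log(18.6), 0.17, 0.122, 0.0),
        ("bmi_z", "identity", (0.067, 0.037, 0.029, -0.080, -0.052),
         0.0, 1.0, 0.126, 0.0),
        ("glucose", "log", (0.003, 0.004, -0.002, 0.001, 0.004),
         np.log(5.05), 0.08, 0.174, 0.735),
        ("insulin", "log", (0.015, 0.015, -0.012, -0.003, -0.016),
         np.log(52.0), 0.60, 0.230, 0.736),
        ("hdl", "log", (-0.002, -0.004, 0.001, 0.002, 0.005),
         np.log(1.45), 0.21, 0.045, 0.413),
        ("ldl", "log", (-0.009, -0.005, -0.002, -0.003, 0.019),
         np.log(2.4), 0.25, 0.050, 0.414),
        ("triglycerides", "log", (0.028, 0.023, -0.002, 0.001, -0.050),
         np.log(0.95), 0.50, 0.068, 0.417),
        ("sbp", "identity", (0.611, 0.443, -0.417, -0.104, -0.532),
         105.0, 12.0, 0.071, 0.198),
        ("dbp", "identity", (0.055, -0.330, -0.332, -0.054, 0.660),
         59.5, 7.0, 0.032, 0.198),
        ("waist", "log", (0.007, 0.003, 0.003, -0.004, -0.009),
         np.log(65.5), 0.14, 0.178, 0.001),
    ]
    age_fx = {"bmi": 0.030, "waist": 0.025, "sbp": 1.2,
              "dbp": 0.5, "insulin": 0.04}
    sex_fx = {"bmi": 0.02, "bmi_z": 0.11, "glucose": -0.02, "insulin": 0.15,
              "hdl": -0.05, "ldl": 0.08, "triglycerides": 0.10, "sbp": -0.5,
              "dbp": 1.0, "waist": -0.018}
    return tuple(_scaled_plant(n, tr, pc, m, sd, r2, miss,
                               age_coef=age_fx.get(n, 0.0),
                               female_coef=sex_fx.get(n, 0.0))
                 for n, tr, pc, m, sd, r2, miss in t4)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines a synthetic cohort (see module docstring)."""

    n_per_sex: Mapping[str, int] = field(
        default_factory=lambda: {"male": 4613, "female": 5325})
    mean_composition: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_COMPOSITION))
    ilr_covariance: Mapping[str, np.ndarray] | None = None
    part_log_sd: Sequence[float] = DEFAULT_PART_LOG_SD
    outcomes: tuple[OutcomePlant, ...] = field(
        default_factory=default_outcome_plants)
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_days: tuple[Sequence[int], Sequence[float]] = DEFAULT_N_DAYS
    day_jitter_sd: float = 0.15
    sleep_jitter_sd: float = 0.04
    vpa_zero_rate: float = 0.02
    invalid_day_rate: float = 0.0
    age_mean: float = 11.4
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.7, "female": 1.8})
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS))

    def covariance(self, sex: str) -> np.ndarray:
        if self.ilr_covariance is not None:
            S = np.asarray(self.ilr_covariance[sex], float)
        else:
            S = default_ilr_covariance(self.part_log_sd)
        if S.shape != (len(PARTS) - 1,) * 2:
            raise ValueError("ILR covariance must be (D-1) x (D-1)")
        eig = np.linalg.eigvalsh(S)
        if eig.min() < -1e-10:
            raise ValueError("ILR covariance is not positive semi-definite")
        return S


@dataclass
class GroundTruth:
    """Planted parameters and bookkeeping; never read by the pipeline."""

    seed: int
    config: GeneratorConfig
    true_compositions: pd.DataFrame          # participant_id + part minutes
    assembled_compositions: pd.DataFrame     # what ingest will reconstruct
    outcome_params: dict[str, dict]          # per outcome: coefs, noise, ...
    planted_invalid_days: pd.DataFrame       # participant_id, day_index
    planted_excluded: pd.DataFrame           # participant_id, reason
    missing_counts: dict[str, int]


def planted_increment_r2(plant: OutcomePlant, cfg: GeneratorConfig,
                         noise_sd: float) -> float:
    """Population compositional-increment R-squared of a plant.

    Increment variance is the within-sex ILR variance explained,
    b' Sigma b; between-sex composition differences are absorbed by the
    sex covariate.  Total variance adds covariate effects (age, sex --
    the sex term includes the shift of the compositional mean) and
    noise.
    """
    b = _CANON.contrast_matrix @ np.asarray(plant.clr_coef, float)
    n = {s: int(cfg.n_per_sex.get(s, 0)) for s in SEXES}
    tot = sum(n.values())
    if tot == 0:
        raise ValueError("empty cohort")
    var_within = sum((n[s] / tot) * float(b @ cfg.covariance(s) @ b)
                     for s in SEXES if n[s] > 0)
    if all(n[s] > 0 for s in SEXES):
        p_f = n["female"] / tot
        mu = {s: float(b @ ilr_transform(_closed_mean(cfg, s), _CANON))
              for s in SEXES}
        sex_shift = (mu["female"] + plant.female_coef) - mu["male"]
        var_between = p_f * (1 - p_f) * sex_shift ** 2
    else:
        var_between = 0.0
    age_var = sum(n[s] * cfg.age_sd[s] ** 2 for s in SEXES if n[s] > 0) / tot
    var_age = plant.age_coef ** 2 * age_var
    total = var_within + var_between + var_age + noise_sd ** 2
    return var_within / total


def solve_noise_sd(plant: OutcomePlant, cfg: GeneratorConfig) -> float:
    """Noise SD achieving the plant's target increment R-squared."""
    if plant.noise_sd is not None:
        return plant.noise_sd
    b = _CANON.contrast_matrix @ np.asarray(plant.clr_coef, float)
    n = {s: cfg.n_per_sex[s] for s in SEXES}
    tot = n["male"] + n["female"]
    var_within = sum((n[s] / tot) * float(b @ cfg.covariance(s) @ b)
                     for s in SEXES)
    # invert planted_increment_r2 for the noise variance
    target = plant.target_r2
    other = (planted_increment_r2(plant, cfg, 0.0))
    # var_within / (var_within + var_other + sigma^2) = target
    var_other = var_within / other - var_within if other > 0 else 0.0
    sigma2 = var_within * (1.0 - target) / target - var_other
    if sigma2 <= 0:
        raise ValueError(f"{plant.spec.name}: target R2 {target} unreachable "
                         "given covariate effects")
    return float(np.sqrt(sigma2))


def _closed_mean(cfg: GeneratorConfig, sex: str) -> Composition:
    v = np.asarray(cfg.mean_composition[sex], float)
    return Composition(v * (DAY_MINUTES / v.sum()))


def generate_cohort(cfg: GeneratorConfig, seed: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate daily records, a demographics/outcomes table and truth.

    Same seed, same config: bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    frames, truth_comp = [], []
    for sex in SEXES:
        n = int(cfg.n_per_sex.get(sex, 0))
        if n == 0:
            continue
        mean = _closed_mean(cfg, sex)
        mu = ilr_transform(mean, _CANON)
        Z = rng.multivariate_normal(mu, cfg.covariance(sex), size=n,
                                    check_valid="ignore")
        comps = ilr_inverse(Z, _CANON)
        df = pd.DataFrame(comps, columns=[f"true_{c}" for c in PART_COLUMNS])
        df["sex"] = sex
        df["age"] = np.clip(rng.normal(cfg.age_mean, cfg.age_sd[sex], n),
                            6.0, 18.0)
        eth = list(cfg.ethnicity_probs)
        p = np.asarray(list(cfg.ethnicity_probs.values()), float)
        df["ethnicity"] = rng.choice(eth, size=n, p=p / p.sum())
        df["month"] = rng.integers(1, 13, size=n)
        frames.append(df)
    participants = pd.concat(frames, ignore_index=True)
    N = len(participants)
    participants.insert(0, "participant_id",
                        [f"P{i:06d}" for i in range(N)])

    # --- split each participant into monitored days -----------------------
    support, probs = cfg.n_days
    n_days = rng.choice(support, size=N, p=probs)
    idx = np.repeat(np.arange(N), n_days)
    total_days = idx.size
    starts = np.concatenate([[0], np.cumsum(n_days)[:-1]])
    day_index = np.arange(total_days) - np.repeat(starts, n_days)

    true_parts = participants[[f"true_{c}" for c in PART_COLUMNS]].to_numpy()
    waking = true_parts[idx, :4] * np.exp(
        rng.normal(0.0, cfg.day_jitter_sd, size=(total_days, 4)))
    if cfg.vpa_zero_rate > 0:
        waking[rng.random(total_days) < cfg.vpa_zero_rate, 3] = 0.0
    sleep = true_parts[idx, 4] * np.exp(
        rng.normal(0.0, cfg.sleep_jitter_sd, size=total_days))
    wear = waking.sum(axis=1)

    planted_invalid = np.zeros(total_days, dtype=bool)
    if cfg.invalid_day_rate > 0:
        planted_invalid = rng.random(total_days) < cfg.invalid_day_rate
        wear = np.where(planted_invalid,
                        rng.uniform(200.0, cfg.filter.min_wear_minutes_per_day
                                    - 10.0, size=total_days), wear)

    days = pd.DataFrame({
        "participant_id": participants["participant_id"].to_numpy()[idx],
        "day_index": day_index,
        "wear_minutes": wear,
        "sed": waking[:, 0], "lpa": waking[:, 1],
        "mpa": waking[:, 2], "vpa": waking[:, 3],
        "sleep": sleep,
        "month": participants["month"].to_numpy()[idx],
    })

    demographics = participants[["participant_id", "sex", "age",
                                 "ethnicity"]].copy()

    # --- outcomes from the compositions the pipeline will assemble --------
    records, _, part_excl, _ = build_cohort(days, demographics,
                                            replace(cfg.filter,
                                                    require_outcome=()))
    assembled = participants[["participant_id"]].merge(
        records[["participant_id", *PART_COLUMNS]], how="left",
        on="participant_id")
    # excluded participants fall back to their true composition
    for c in PART_COLUMNS:
        assembled[c] = assembled[c].fillna(
            pd.Series(true_parts[:, PART_COLUMNS.index(c)],
                      index=assembled.index))
    Z_eff = ilr_transform(assembled[list(PART_COLUMNS)].to_numpy(), _CANON)

    female = (participants["sex"] == "female").to_numpy(float)
    age_c = participants["age"].to_numpy() - cfg.age_mean
    outcome_params: dict[str, dict] = {}
    missing_counts: dict[str, int] = {}
    both_sexes = 0 < female.sum() < N
    for plant in cfg.outcomes:
        sd = solve_noise_sd(plant, cfg)
        b = _CANON.contrast_matrix @ np.asarray(plant.clr_coef, float)
        m = Z_eff @ b
        # realized variance decomposition (assembled coordinates, this draw)
        if both_sexes:
            p_f = female.mean()
            v_within = ((1 - p_f) * np.var(m[female == 0], ddof=1)
                        + p_f * np.var(m[female == 1], ddof=1))
            shift = (m[female == 1].mean() + plant.female_coef
                     - m[female == 0].mean())
            v_between = p_f * (1 - p_f) * shift ** 2
        else:
            v_within, v_between = float(np.var(m, ddof=1)), 0.0
        v_age = plant.age_coef ** 2 * float(np.var(age_c, ddof=1))
        r2_realized = v_within / (v_within + v_between + v_age + sd ** 2)
        y = (plant.mean_level + m + plant.age_coef * age_c
             + plant.female_coef * female)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=N)
        if plant.spec.transform == "log":
            y = np.exp(y)
        if plant.missing_rate > 0:
            miss = rng.random(N) < plant.missing_rate
            y = np.where(miss, np.nan, y)
            missing_counts[plant.spec.name] = int(miss.sum())
        else:
            missing_counts[plant.spec.name] = 0
        demographics[plant.spec.column] = y
        outcome_params[plant.spec.name] = {
            "transform": plant.spec.transform,
            "clr_coef": list(plant.clr_coef),
            "ilr_coef": b.tolist(),
            "pivot_coef": pivot_coefficients_from_clr(
                np.asarray(plant.clr_coef)),
            "noise_sd": sd,
            "mean_level": plant.mean_level,
            "age_coef": plant.age_coef,
            "female_coef": plant.female_coef,
            "increment_r2_target": planted_increment_r2(plant, cfg, sd),
            "increment_r2_realized": r2_realized,
        }

    truth = GroundTruth(
        seed=seed, config=cfg,
        true_compositions=pd.concat(
            [participants[["participant_id"]],
             pd.DataFrame(true_parts, columns=list(PART_COLUMNS))], axis=1),
        assembled_compositions=assembled,
        outcome_params=outcome_params,
        planted_invalid_days=days.loc[planted_invalid,
                                      ["participant_id", "day_index"]]
        .reset_index(drop=True),
        planted_excluded=part_excl,
        missing_counts=missing_counts)
    return days, demographics, truth


# --- exact participant-flow cohorts --------------------------------------

def generate_flow_cohort(n_total: int, n_excluded: int, seed: int,
                         cfg: GeneratorConfig | None = None,
                         wear_fraction: float = 0.7
                         ) -> tuple[pd.DataFrame, pd.DataFrame, FilterConfig,
                                    GroundTruth]:
    """A cohort in which exactly ``n_excluded`` participants fail.

    Failures are planted as all-days-below-wear-threshold (a
    ``wear_fraction`` share) or as missing the required outcome; every
    other participant is guaranteed to pass the returned FilterConfig,
    so the pipeline retains exactly ``n_total - n_excluded`` records.
    """
    if not 0 <= n_excluded <= n_total:
        raise ValueError("need 0 <= n_excluded <= n_total")
    if cfg is None:
        cfg = GeneratorConfig()
    n_keep = n_total - n_excluded
    # retained counts follow the configured sex ratio; excess split evenly
    keep_f = round(n_keep * cfg.n_per_sex["female"]
                   / sum(cfg.n_per_sex.values()))
    n_female = keep_f + n_excluded // 2
    n_male = n_total - n_female
    fcfg = replace(cfg.filter, require_outcome=("bmi",))
    cfg = replace(cfg, n_per_sex={"male": n_male, "female": n_female},
                  filter=fcfg, invalid_day_rate=0.0)
    days, demo, truth = generate_cohort(cfg, seed)

    rng = np.random.default_rng(seed + 1)
    ids = demo["participant_id"].to_numpy()
    planted = rng.choice(ids, size=n_excluded, replace=False)
    n_wear = int(round(n_excluded * wear_fraction))
    wear_ids, outcome_ids = set(planted[:n_wear]), set(planted[n_wear:])

    in_wear = days["participant_id"].isin(wear_ids).to_numpy()
    days.loc[in_wear, "wear_minutes"] = rng.uniform(
        200.0, fcfg.min_wear_minutes_per_day - 10.0, size=in_wear.sum())
    demo.loc[demo["participant_id"].isin(outcome_ids), "bmi"] = np.nan

    # guarantee the rest pass: clamp accidental wear/sleep violations
    ok = ~days["participant_id"].isin(planted)
    days.loc[ok, "wear_minutes"] = days.loc[ok, "wear_minutes"].clip(
        lower=fcfg.min_wear_minutes_per_day)
    lo, hi = fcfg.sleep_bounds
    days.loc[ok, "sleep"] = days.loc[ok, "sleep"].clip(lo + 1.0, hi - 1.0)

    truth.planted_excluded = pd.DataFrame({
        "participant_id": list(planted),
        "reason": ["wear_time"] * n_wear
                  + ["missing_outcome"] * (n_excluded - n_wear)})
    return days, demo, fcfg, truth


# --- validation: recovery and calibration --------------------------------

def make_validation_config(n_per_sex: int = 2000) -> GeneratorConfig:
    """Single-outcome config for coefficient-recovery and coverage studies.

    Designed for measurement precision rather than realism: an isotropic
    ILR covariance identifies every pivot balance equally well, and the
    balanced zero-sum coefficient vector with a 0.30 compositional
    variance share keeps the Monte-Carlo noise of per-coefficient bias
    estimates far below the bounds the recovery study checks.
    """
    plant = OutcomePlant(
        OutcomeSpec("cmr_score", "identity"),
        clr_coef=(1.0, 1.0, -2 / 3, -2 / 3, -2 / 3), mean_level=50.0,
        age_coef=0.3, female_coef=1.0, target_r2=0.30)
    iso = 0.35 ** 2 * np.eye(len(PARTS) - 1)
    return GeneratorConfig(
        n_per_sex={"male": n_per_sex, "female": n_per_sex},
        ilr_covariance={"male": iso, "female": iso},
        outcomes=(plant,))


def _analytic_percent_matrix(clr_coef: np.ndarray, transform: str,
                             reference: Composition, outcome_mean: float,
                             delta: float = 10.0) -> pd.DataFrame:
    """Change matrix implied directly by planted coefficients."""
    from .reallocation import InfeasibleReallocation, ReallocationSpec, \
        reallocate
    b = _CANON.contrast_matrix @ np.asarray(clr_coef, float)
    z0 = ilr_transform(reference, _CANON)
    parts = list(reference.parts)
    out = pd.DataFrame(np.nan, index=parts, columns=parts)
    for donor in parts:
        for receiver in parts:
            if donor == receiver:
                continue
            try:
                moved = reallocate(reference,
                                   ReallocationSpec(donor, receiver, delta))
            except InfeasibleReallocation:
                continue
            dy = float(b @ (ilr_transform(moved, _CANON) - z0))
            out.loc[receiver, donor] = (100.0 * np.expm1(dy)
                                        if transform == "log"
                                        else 100.0 * dy / outcome_mean)
    return out


def coefficient_recovery(n_per_sex: int = 2000, n_replicates: int = 200,
                         seed: int = 0,
                         cfg: GeneratorConfig | None = None) -> dict:
    """Monte-Carlo recovery of planted pivot coefficients.

    Runs the full pipeline (days -> ingest -> model) per replicate and
    reports 95% CI coverage pooled over behaviours, per-behaviour
    relative bias and RMSE.
    """
    if cfg is None:
        cfg = make_validation_config(n_per_sex)
    plant = cfg.outcomes[0]
    true_pivot = pivot_coefficients_from_clr(np.asarray(plant.clr_coef))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_replicates)]
    estimates = {b: [] for b in PARTS}
    covered = total = 0
    for rep_seed in seeds:
        days, demo, _ = generate_cohort(cfg, rep_seed)
        records, _, _, _ = build_cohort(days, demo, cfg.filter)
        fit = fit_compositional_model(records, plant.spec)
        for b in PARTS:
            pc = fit.behaviours[b]
            estimates[b].append(pc.coefficient)
            covered += int(pc.ci_low <= true_pivot[b] <= pc.ci_high)
            total += 1
    report = {"n_per_sex": n_per_sex, "n_replicates": n_replicates,
              "coverage": covered / total,
              "true_pivot": true_pivot, "bias": {}, "relative_bias": {},
              "rmse": {}}
    for b in PARTS:
        est = np.asarray(estimates[b])
        bias = float(est.mean() - true_pivot[b])
        report["bias"][b] = bias
        report["relative_bias"][b] = bias / abs(true_pivot[b])
        report["rmse"][b] = float(np.sqrt(np.mean((est - true_pivot[b]) ** 2)))
    report["max_abs_relative_bias"] = max(
        abs(v) for v in report["relative_bias"].values())
    return report


def change_matrix_consistency(sizes: Sequence[int] = (500, 2000, 8000),
                              n_replicates: int = 8, seed: int = 0) -> dict:
    """Pipeline vs analytic change matrices as n grows.

    For each cohort size, the mean (over replicates) of the maximum
    absolute discrepancy between the pipeline's percent change matrix
    and the analytic matrix implied by the planted coefficients; the
    sequence should shrink with n.
    """
    from .reallocation import change_matrix, compute_swc
    results = {}
    ss = np.random.SeedSequence(seed)
    for size, child in zip(sizes, ss.spawn(len(sizes))):
        cfg = make_validation_config(size)
        plant = cfg.outcomes[0]
        reps = []
        for sub in child.spawn(n_replicates):
            rep_seed = int(sub.generate_state(1)[0] % (2 ** 31))
            days, demo, _ = generate_cohort(cfg, rep_seed)
            records, _, _, _ = build_cohort(days, demo, cfg.filter)
            fit = fit_compositional_model(records, plant.spec)
            ref = geometric_mean_composition(
                records[list(PART_COLUMNS)].to_numpy())
            swc = compute_swc(records[plant.spec.column].to_numpy(),
                              plant.spec.name)
            cm = change_matrix(fit, ref, swc)
            analytic = _analytic_percent_matrix(
                np.asarray(plant.clr_coef), plant.spec.transform, ref,
                fit.outcome_mean)
            diff = (cm.percent - analytic).abs().to_numpy()
            reps.append(float(np.nanmax(diff)))
        results[size] = float(np.mean(reps))
    return {"max_discrepancy_by_n": results,
            "shrinks_with_n": all(
                results[a] > results[b]
                for a, b in zip(sizes[:-1], sizes[1:]))}


def type_i_error_rate(n_sims: int = 1000, n_participants: int = 250,
                      seed: int = 0) -> dict:
    """Rejection rate of the compositional F test under the null.

    Outcomes are generated with a zero CLR coefficient vector, so the
    composition carries no signal; the F test of the four ILR
    coordinates should reject at the nominal 5% rate.
    """
    plant = OutcomePlant(OutcomeSpec("null_score", "identity"),
                         clr_coef=(0.0,) * len(PARTS), mean_level=0.0,
                         age_coef=0.2, female_coef=0.5, noise_sd=1.0)
    cfg = GeneratorConfig(
        n_per_sex={"male": n_participants // 2,
                   "female": n_participants - n_participants // 2},
        outcomes=(plant,))
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for sub in ss.spawn(n_sims):
        sim_seed = int(sub.generate_state(1)[0] % (2 ** 31))
        days, demo, _ = generate_cohort(cfg, sim_seed)
        records, _, _, _ = build_cohort(days, demo, cfg.filter)
        fit = fit_compositional_model(records, plant.spec, fit_pivots=False)
        rejections += int(fit.model_p < 0.05)
    rate = rejections / n_sims
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
    return {"n_sims": n_sims, "rejection_rate": rate,
            "binomial_interval": (0.05 - half, 0.05 + half),
            "within_interval": abs(rate - 0.05) <= half}


def recovery_report(seed: int = 0, n_per_sex: int = 2000,
                    n_replicates: int = 200,
                    sizes: Sequence[int] = (500, 2000, 8000)) -> dict:
    """Full synthetic-validation bundle: coverage/bias/RMSE of pivot
    coefficients plus change-matrix consistency."""
    rec = coefficient_recovery(n_per_sex, n_replicates, seed)
    cons = change_matrix_consistency(sizes, seed=seed + 1)
    return {"coefficient_recovery": rec, "change_matrix": cons}
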