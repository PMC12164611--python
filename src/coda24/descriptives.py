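"""Cohort descriptives: sex comparisons, movement summaries, variation.

Covers covariate-adjusted sex comparisons (one-way ANCOVA with Cohen's
d and the trivial/moderate/large/very-large banding), the per-behaviour
summary of overall mean, geometric mean and percent of the 24-h day,
and the pairwise log-ratio variation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import PARTS, geometric_mean_composition, variation_matrix
from .models import PART_COLUMNS, _check_full_rank, _dummy_code

ETHNICITY_LEVELS = ("White", "Black", "Asian", "NotReported")

# |d| bands on the value rounded to 2 dp: <=0.20 trivial, 0.21-0.60
# moderate, 0.61-0.80 large, >=0.81 very large (half-open intervals
# close the printed gaps).
_BAND_EDGES = (0.205, 0.605, 0.805)
_BAND_NAMES = ("trivial", "moderate", "large", "very large")


def effect_band(d: float) -> str:
    """Qualitative effect-size band for a Cohen's d value."""
    mag = round(abs(float(d)), 2)
    for edge, name in zip(_BAND_EDGES, _BAND_NAMES):
        if mag < edge:
            return name
    return _BAND_NAMES[-1]


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    band: str


def cohens_d_from_stats(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> EffectSize:
    """Cohen's d with pooled (n-1 weighted) SD and normal-approximation CI."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                     / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: d undefined")
    d = (mean1 - mean2) / pooled
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    return EffectSize(float(d), float(d - 1.96 * se), float(d + 1.96 * se),
                      effect_band(d))


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> EffectSize:
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    return cohens_d_from_stats(g1.mean(), g1.std(ddof=1), g1.size,
                               g2.mean(), g2.std(ddof=1), g2.size)


@dataclass(frozen=True)
class SexComparison:
    """ANCOVA-adjusted female-vs-male comparison of one outcome."""

    outcome: str
    n_male: int
    n_female: int
    adjusted_mean_male: float
    adjusted_mean_female: float
    mean_difference: float        # female minus male, covariate-adjusted
    f_stat: float
    p_value: float
    d_raw: EffectSize             # from raw group means/SDs
    d_adjusted: EffectSize        # adjusted difference / residual SD


def ancova_sex_comparison(records: pd.DataFrame, outcome: str,
                          covariates: tuple[str, ...] = ("age", "ethnicity")
                          ) -> SexComparison:
    """One-way ANCOVA of an outcome on sex, adjusted for covariates.

    The F statistic for sex is the squared t of the sex dummy in the
    equivalent linear model.  Adjusted means are least-squares means:
    predictions for each sex at the sample-average covariate values.
    """
    cols = [outcome, "sex", *covariates]
    data = records.dropna(subset=[c for c in cols if c in records.columns])
    counts = data["sex"].value_counts()
    if counts.get("male", 0) < 2 or counts.get("female", 0) < 2:
        raise ValueError("need at least two participants per sex")

    y = data[outcome].to_numpy(dtype=float)
    design, _ = _dummy_code(data, ("sex", *covariates), {"sex": "male"})
    design.insert(0, "const", 1.0)
    _check_full_rank(design)
    res = sm.OLS(y, design).fit()

    sex_col = "sex[female]"
    diff = float(res.params[sex_col])
    t = float(res.tvalues[sex_col])
    f_stat, p = t ** 2, float(res.pvalues[sex_col])

    at_means = design.mean()
    at_means[sex_col] = 0.0
    adj_male = float(res.params @ at_means)
    adj_female = adj_male + diff

    male = data.loc[data["sex"] == "male", outcome].to_numpy(dtype=float)
    female = data.loc[data["sex"] == "female", outcome].to_numpy(dtype=float)
    d_raw = cohens_d(female, male)

    resid_sd = float(np.sqrt(res.scale))
    d_adj_val = diff / resid_sd
    se = np.sqrt((len(male) + len(female)) / (len(male) * len(female))
                 + d_adj_val ** 2 / (2 * (len(male) + len(female))))
    d_adj = EffectSize(d_adj_val, d_adj_val - 1.96 * se, d_adj_val + 1.96 * se,
                       effect_band(d_adj_val))

    return SexComparison(outcome, int(len(male)), int(len(female)),
                         adj_male, adj_female, diff, f_stat, p, d_raw, d_adj)


def sex_comparison_table(records: pd.DataFrame, outcomes: list[str],
                         covariates: tuple[str, ...] = ("age", "ethnicity")
                         ) -> pd.DataFrame:
    rows = []
    for out in outcomes:
        c = ancova_sex_comparison(records, out, covariates)
        rows.append({
            "outcome": out, "n_male": c.n_male, "n_female": c.n_female,
            "adj_mean_male": c.adjusted_mean_male,
            "adj_mean_female": c.adjusted_mean_female,
            "difference": c.mean_difference, "F": c.f_stat, "p": c.p_value,
            "d": c.d_adjusted.d, "d_ci_low": c.d_adjusted.ci_low,
            "d_ci_high": c.d_adjusted.ci_high, "band": c.d_adjusted.band,
            "d_raw": c.d_raw.d, "significant": c.p_value < 0.05,
        })
    return pd.DataFrame(rows)


def movement_summary(records: pd.DataFrame, by_sex: bool = True
                     ) -> pd.DataFrame:
    """Overall mean, geometric mean and % of 24 h per behaviour.

    The overall-mean column averages raw (pre-closure) minutes when the
    ingest step stored them (``raw_*`` columns) and closed minutes
    otherwise, so it need not sum to 1440; the geometric-mean column is
    the compositional centre and always does.
    """
    groups = records.groupby("sex", observed=True) if by_sex \
        else [("all", records)]
    rows = []
    for label, grp in groups:
        raw_cols = [f"raw_{c}" for c in PART_COLUMNS]
        raw = grp[raw_cols] if all(c in grp.columns for c in raw_cols) \
            else grp[list(PART_COLUMNS)]
        centre = geometric_mean_composition(
            grp[list(PART_COLUMNS)].to_numpy(dtype=float))
        for part, col, gm, pct in zip(PARTS, raw.columns, centre.values,
                                      centre.percent_of_day()):
            rows.append({"group": label, "behaviour": part,
                         "overall_mean": float(raw[col].mean()),
                         "geometric_mean": float(gm),
                         "percent_of_day": float(pct)})
    return pd.DataFrame(rows)


def variation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise log-ratio variation matrix of the cohort, as a table."""
    vm = variation_matrix(records[list(PART_COLUMNS)].to_numpy(dtype=float),
                          parts=PARTS)
    return pd.DataFrame(vm.entries, index=vm.labels, columns=vm.labels)
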