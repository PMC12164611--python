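"""Cohort assembly: valid-day filtering and participant-level averaging.

Daily accelerometer summaries (SED/LPA/MPA/VPA minutes plus
self-reported sleep) are filtered on wear time and sleep plausibility,
averaged within participant, reconciled to a 1440-minute day by
proportionally rescaling the waking behaviours to 1440 minus mean
sleep, zero-replaced and closed.  Every drop is logged with a reason
code so retained + excluded always equals the input count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, zero_replace

DAY_COLUMNS = ("participant_id", "day_index", "wear_minutes",
               "sed", "lpa", "mpa", "vpa", "sleep", "month")
WAKING = ("sed", "lpa", "mpa", "vpa")
DEMO_COLUMNS = ("participant_id", "sex", "age", "ethnicity")


@dataclass(frozen=True)
class FilterConfig:
    """Valid-day and participant-retention rules.

    Defaults (600 min wear, 3 valid days, sleep in [240, 960] min) stand
    in for study-specific criteria and are fully configurable.
    ``require_outcome``: participants missing *all* of these outcome
    columns are excluded (empty set disables the rule).
    """

    min_wear_minutes_per_day: float = 600.0
    min_valid_days: int = 3
    require_outcome: tuple[str, ...] = ()
    sleep_bounds: tuple[float, float] = (240.0, 960.0)
    zero_strategy: str = "fixed_floor"
    zero_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.min_valid_days < 1:
            raise ValueError("min_valid_days must be >= 1")
        lo, hi = self.sleep_bounds
        if lo > hi:
            raise ValueError("sleep_bounds must be ordered")


def load_daily_csv(path) -> pd.DataFrame:
    days = pd.read_csv(path)
    missing = [c for c in DAY_COLUMNS if c not in days.columns]
    if missing:
        raise KeyError(f"daily table missing columns: {missing}")
    return days


def load_demographics_csv(path) -> pd.DataFrame:
    demo = pd.read_csv(path)
    missing = [c for c in DEMO_COLUMNS if c not in demo.columns]
    if missing:
        raise KeyError(f"demographics table missing columns: {missing}")
    return demo


def filter_valid_days(days: pd.DataFrame, cfg: FilterConfig = FilterConfig()
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split daily records into valid days and an exclusion log.

    Reasons (checked on every row, reported with fixed priority):
    ``malformed`` (negative/NaN minutes, wear or sleep above 1440),
    ``wear_time`` (below the wear threshold), ``sleep_bounds``.
    The retained set is independent of rule order.
    """
    minute_cols = ["wear_minutes", *WAKING, "sleep"]
    vals = days[minute_cols].apply(pd.to_numeric, errors="coerce")
    malformed = (vals.isna().any(axis=1) | (vals < 0).any(axis=1)
                 | (vals["wear_minutes"] > DAY_MINUTES)
                 | (vals["sleep"] > DAY_MINUTES))
    low_wear = ~malformed & (vals["wear_minutes"] < cfg.min_wear_minutes_per_day)
    lo, hi = cfg.sleep_bounds
    bad_sleep = ~malformed & ((vals["sleep"] < lo) | (vals["sleep"] > hi))

    reason = np.full(len(days), "", dtype=object)
    reason[bad_sleep.to_numpy()] = "sleep_bounds"
    reason[low_wear.to_numpy()] = "wear_time"
    reason[malformed.to_numpy()] = "malformed"
    keep = reason == ""

    excluded = days.loc[~keep, ["participant_id", "day_index"]].copy()
    excluded["reason"] = reason[~keep]
    return days.loc[keep].copy(), excluded.reset_index(drop=True)


def _modal_month(valid_days: pd.DataFrame) -> pd.Series:
    """Modal monitoring month per participant; ties go to the earliest."""
    counts = (valid_days.groupby(["participant_id", "month"]).size()
              .reset_index(name="n_days")
              .sort_values(["participant_id", "n_days", "month"],
                           ascending=[True, False, True]))
    modal = counts.drop_duplicates("participant_id")
    return modal.set_index("participant_id")["month"]


def assemble_participants(valid_days: pd.DataFrame, demographics: pd.DataFrame,
                          cfg: FilterConfig = FilterConfig()
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average valid days within participant into analysis-ready records.

    Per participant: mean minutes per behaviour across valid days; the
    four waking behaviours rescaled by (1440 - mean sleep) / (their
    sum); zeros floored; closed to 1440.  Returns the records table and
    a participant-level exclusion log (``too_few_days``,
    ``missing_outcome``).
    """
    if demographics["participant_id"].duplicated().any():
        raise ValueError("duplicate participant_id in demographics")
    demo = demographics.set_index("participant_id")

    agg = valid_days.groupby("participant_id").agg(
        n_valid_days=("day_index", "size"),
        **{c: (c, "mean") for c in (*WAKING, "sleep")})
    agg = agg.reindex(demo.index).fillna({"n_valid_days": 0})
    agg["n_valid_days"] = agg["n_valid_days"].astype(int)

    reasons = pd.Series("", index=demo.index, dtype=object)
    reasons[agg["n_valid_days"] < cfg.min_valid_days] = "too_few_days"
    if cfg.require_outcome:
        present = [c for c in cfg.require_outcome if c in demo.columns]
        if present:
            all_missing = demo[present].isna().all(axis=1)
            reasons[(reasons == "") & all_missing] = "missing_outcome"

    keep = reasons == ""
    excluded = pd.DataFrame({"participant_id": demo.index[~keep],
                             "reason": reasons[~keep].to_numpy()})

    kept = agg.loc[keep]
    waking = kept[list(WAKING)].to_numpy(dtype=float)
    sleep = kept["sleep"].to_numpy(dtype=float)
    scale = (DAY_MINUTES - sleep) / waking.sum(axis=1)
    mat = np.column_stack([waking * scale[:, None], sleep])
    # floor zeros (VPA-zero participants are expected), then close to 1440
    floored = np.where(mat == 0, cfg.zero_floor, mat)
    if cfg.zero_strategy == "multiplicative":
        floored = np.vstack([
            zero_replace(row, "multiplicative", cfg.zero_floor) for row in mat])
    closed = floored * (DAY_MINUTES / floored.sum(axis=1, keepdims=True))

    records = demo.loc[keep].reset_index()
    for j, c in enumerate((*WAKING, "sleep")):
        records[c] = closed[:, j]
        records[f"raw_{c}"] = kept[c].to_numpy()  # pre-closure day means
    records["n_valid_days"] = kept["n_valid_days"].to_numpy()
    month = _modal_month(valid_days)
    records["month"] = records["participant_id"].map(month).astype(int)
    return records, excluded.reset_index(drop=True)


def build_cohort(days: pd.DataFrame, demographics: pd.DataFrame,
                 cfg: FilterConfig = FilterConfig()
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Full ingest: day filter, participant assembly, and a flow summary."""
    valid, day_excl = filter_valid_days(days, cfg)
    records, part_excl = assemble_participants(valid, demographics, cfg)
    flow = {
        "participants_in": int(len(demographics)),
        "days_in": int(len(days)),
        "days_excluded": {k: int(v) for k, v in
                          day_excl["reason"].value_counts().items()},
        "participants_excluded": {k: int(v) for k, v in
                                  part_excl["reason"].value_counts().items()},
        "participants_retained": int(len(records)),
    }
    if flow["participants_retained"] + sum(
            flow["participants_excluded"].values()) != flow["participants_in"]:
        raise AssertionError("participant flow does not conserve counts")
    return records, day_excl, part_excl, flow


def write_flow_summary(flow: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(flow, fh, indent=2)
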