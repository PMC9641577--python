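"""Cohort descriptive statistics stratified by 10-year outcome."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["percentage", "round_half_up", "summarize_cohort", "CohortSummary"]

CATEGORICAL = ["sex", "ethnicity", "imd_quintile", "smoking", "alcohol"]
CONTINUOUS = ["age", "sbp", "dbp", "cholesterol", "frailty_index"]
FLAGS = [
    "previous_falls", "memory_problems", "mobility_problems", "stroke",
    "multiple_sclerosis", "acei", "arb", "alpha_blocker", "beta_blocker",
    "ccb", "diuretic", "other_antihypertensive", "opioid",
    "hypnotic_anxiolytic", "antidepressant", "anticholinergic",
]


def round_half_up(x, decimals=1):
    """Round with ties away from zero, matching printed-table convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count, denominator, decimals=1):
    """Percentage of a count over its denominator, half-up rounded."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, decimals)


@dataclass
class CohortSummary:
    n: int
    event_counts: dict
    event_percentages: dict
    median_followup: float
    followup_iqr: tuple
    table: pd.DataFrame = field(repr=False, default=None)


def _stratum_stats(df, variables=None):
    rows = {}
    n = len(df)
    for var in (variables or CONTINUOUS):
        if var in df:
            x = df[var].dropna()
            rows[f"{var} mean (SD)"] = (
                f"{x.mean():.1f} ({x.std(ddof=1):.1f})" if len(x) > 1 else "")
    for var in CATEGORICAL:
        if var not in df:
            continue
        counts = df[var].value_counts(dropna=False)
        for level, cnt in counts.items():
            label = "Missing" if pd.isna(level) else str(level)
            rows[f"{var}: {label}"] = f"{cnt} ({percentage(cnt, n)})"
    for var in FLAGS:
        if var in df:
            cnt = int(df[var].fillna(0).sum())
            rows[var] = f"{cnt} ({percentage(cnt, n)})"
    return rows


def summarize_cohort(patients: pd.DataFrame, outcomes: pd.DataFrame,
                     horizon=10.0):
    """Descriptive summary stratified by outcome type at the horizon.

    Events occurring after the horizon are treated as event-free for the
    stratification.  Counts and percentages (one decimal, half-up), means
    (SD), and median (IQR) follow-up are returned; missing values form
    their own category for categorical variables.
    """
    merged = patients.merge(outcomes, on="patient_id")
    n = len(merged)
    within = merged["time"] <= horizon
    is_fall = (merged["event"] == 1) & within
    is_death = (merged["event"] == 2) & within
    event_counts = {
        "n": n,
        "falls": int(is_fall.sum()),
        "deaths": int(is_death.sum()),
        "event_free": int(n - is_fall.sum() - is_death.sum()),
    }
    event_pct = {
        "falls": percentage(event_counts["falls"], n),
        "deaths": percentage(event_counts["deaths"], n),
    }
    fu = merged["time"].clip(upper=horizon)
    med = float(np.median(fu)) if n else float("nan")
    iqr = (float(np.percentile(fu, 25)), float(np.percentile(fu, 75))) \
        if n else (float("nan"), float("nan"))

    strata = {
        "total": merged,
        "falls": merged[is_fall],
        "deaths": merged[is_death],
    }
    table = pd.DataFrame({k: pd.Series(_stratum_stats(v))
                          for k, v in strata.items()})
    return CohortSummary(n=n, event_counts=event_counts,
                         event_percentages=event_pct,
                         median_followup=med, followup_iqr=iqr, table=table)
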