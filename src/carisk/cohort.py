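"""Cohort construction: dichotomization, selection and summary of test records.

Raw pathology records become one analysis record per person per risk factor:
the most recent in-window test is kept, records with incomplete details are
excluded (with a per-reason log), and test values are dichotomized into
higher/lower risk by established guideline cut-points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .region import STUDY_WINDOW

__all__ = [
    "RiskRule",
    "RISK_RULES",
    "classify_risk",
    "select_most_recent",
    "exclude_incomplete",
    "risk_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskRule:
    """A single dichotomization rule: direction, cut-point, unit, label."""

    op: str  # one of ">=", ">", "<"
    threshold: float
    unit: str
    label: str


#: Guideline cut-points for the seven risk factors. Boundary semantics
#: follow the printed rules exactly: e.g. FBSL 7.0 is higher risk (>=),
#: HbA1c 7.5 is not (strict >), HDL 1.0 and eGFR 60 are not (strict <).
RISK_RULES: dict[str, RiskRule] = {
    "FBSL": RiskRule(">=", 7.0, "mmol/L", "High FBSL"),
    "HbA1c": RiskRule(">", 7.5, "%", "High HbA1c"),
    "TC": RiskRule(">=", 5.5, "mmol/L", "High TC"),
    "HDL": RiskRule("<", 1.0, "mmol/L", "Low HDL"),
    "ACR": RiskRule(">=", 30.0, "mcg/L to mg/L", "High ACR"),
    "eGFR": RiskRule("<", 60.0, "mL/min/1.73 m^2", "Low eGFR"),
    "BMI": RiskRule(">=", 30.0, "kg/m^2", "Obesity"),
}

_OPS = {">=": np.greater_equal, ">": np.greater, "<": np.less}


def classify_risk(cmrf: str, value):
    """Dichotomize a test value (scalar or array) for one risk factor.

    Returns booleans: True = higher risk. Raises for unknown risk factors
    or non-finite scalar values.
    """
    try:
        rule = RISK_RULES[cmrf]
    except KeyError:
        raise ValueError(f"unknown CMRF {cmrf!r}; expected one of {sorted(RISK_RULES)}")
    arr = np.asarray(value, float)
    if arr.ndim == 0 and not np.isfinite(arr):
        raise ValueError(f"non-finite test value for {cmrf}: {value!r}")
    res = _OPS[rule.op](arr, rule.threshold)
    return bool(res) if np.ndim(value) == 0 else res


def select_most_recent(
    records: pd.DataFrame, window: tuple[date, date] = STUDY_WINDOW
) -> pd.DataFrame:
    """Keep the latest in-window record per (person, CMRF).

    Out-of-window records are dropped first; ties on the latest date break
    deterministically on the highest record_id. Dropped counts are logged.
    """
    dates = pd.to_datetime(records["test_date"])
    start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
    in_window = (dates >= start) & (dates <= end)
    n_out = int((~in_window).sum())
    kept = records[in_window]
    kept = kept.sort_values(["test_date", "record_id"], kind="mergesort")
    dedup = kept.drop_duplicates(subset=["person_id", "cmrf"], keep="last")
    n_earlier = len(kept) - len(dedup)
    if n_out or n_earlier:
        log.info(
            "select_most_recent: dropped %d out-of-window and %d superseded record(s)",
            n_out, n_earlier,
        )
    return dedup.reset_index(drop=True)


def exclude_incomplete(
    records: pd.DataFrame, areas: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records with incomplete details; return (retained, reason counts).

    A record is incomplete if it misses sex, age group, a resolvable area
    link, a usable value (neither test_value nor an already-dichotomized
    higher_risk), or if its area lacks a disadvantage score. Each record is
    counted once under the first matching reason.
    """
    irsd_ok = set(areas.loc[areas["irsd"].notna(), "area_id"])
    known = set(areas["area_id"])

    sex_bad = records["sex"].isna().to_numpy()
    age_bad = records["age_group"].isna().to_numpy()
    link_bad = ~records["area_id"].isin(known).to_numpy()
    value_bad = (records["test_value"].isna() & records["higher_risk"].isna()).to_numpy()
    irsd_bad = ~records["area_id"].isin(irsd_ok).to_numpy() & ~link_bad

    reasons = {}
    remaining = np.zeros(len(records), dtype=bool)
    for name, mask in [
        ("sex", sex_bad), ("age_group", age_bad), ("area_link", link_bad),
        ("value", value_bad), ("area_irsd", irsd_bad),
    ]:
        hit = mask & ~remaining
        reasons[name] = int(hit.sum())
        remaining |= mask
    retained = records[~remaining].reset_index(drop=True)
    n_drop = int(remaining.sum())
    if n_drop:
        log.info("exclude_incomplete: dropped %d record(s): %s", n_drop, reasons)
    return retained, reasons


def risk_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-CMRF higher-risk counts and percentages, split by sex.

    Requires dichotomized records (higher_risk set). Percentages use that
    CMRF's test count as denominator and are reported to one decimal.
    """
    if records["higher_risk"].isna().any():
        raise ValueError("records must be dichotomized (higher_risk set)")
    rows = []
    for cmrf, grp in records.groupby("cmrf", sort=False):
        n = len(grp)
        hi = grp[grp["higher_risk"] == 1]
        n_hi = len(hi)
        n_m = int((hi["sex"] == "male").sum())
        n_f = n_hi - n_m
        rows.append({
            "cmrf": cmrf,
            "label": RISK_RULES[cmrf].label if cmrf in RISK_RULES else cmrf,
            "n_tests": n,
            "n_higher_risk": n_hi,
            "pct_higher_risk": round(100.0 * n_hi / n, 1) if n else 0.0,
            "n_male_higher": n_m,
            "pct_male": round(100.0 * n_m / n, 1) if n else 0.0,
            "n_female_higher": n_f,
            "pct_female": round(100.0 * n_f / n, 1) if n else 0.0,
        })
    return pd.DataFrame(rows)
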