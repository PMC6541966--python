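"""Behavioral scoring: paw-withdrawal thresholds and CPA scores.

PWT rule: five probe readings are taken per subject and timepoint; the
first is discarded and the remaining four averaged.

CPA score: time spent in the pain-paired compartment on a test day minus
at baseline (seconds; negative values mean aversion of the pain-paired
compartment). Non-pain-paired scores can be requested explicitly but are
not part of the default output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import validate_cpa, validate_pwt

__all__ = ["pwt_score", "pwt_scores_table", "cpa_score", "cpa_scores_table",
           "DataError"]


class DataError(ValueError):
    """Required rows are missing from a behavioral table."""


def pwt_score(measurements) -> float:
    """Threshold (grams) from five ordered readings: mean of readings 2-5."""
    values = np.asarray(measurements, dtype=float)
    if values.shape != (5,):
        raise ValueError(
            f"expected exactly 5 measurements in acquisition order, got {values.size}"
        )
    return float(values[1:].mean())


def pwt_scores_table(pwt: pd.DataFrame) -> pd.DataFrame:
    """Per subject x timepoint PWT scores from a long-format readings table."""
    pwt = validate_pwt(pwt)
    rows = []
    for (subject, group, timepoint), grp in pwt.groupby(
        ["subject", "group", "timepoint"], sort=False
    ):
        ordered = grp.sort_values("trial_index")["grams"].to_numpy()
        rows.append((subject, group, timepoint, pwt_score(ordered)))
    return pd.DataFrame(rows, columns=["subject", "group", "timepoint", "pwt_grams"])


def _pain_paired_occupancy(cpa: pd.DataFrame, subject: str, day: str,
                           compartment: str) -> float:
    rows = cpa[
        (cpa["subject"] == subject)
        & (cpa["day"].astype(str) == str(day))
        & (cpa["compartment"] == compartment)
    ]
    if rows.empty:
        raise DataError(
            f"subject {subject!r}: no {compartment} occupancy row for day {day!r}"
        )
    return float(rows["occupancy_s"].iloc[0])


def cpa_score(
    cpa: pd.DataFrame, subject: str, day: str, compartment: str = "pain_paired"
) -> float:
    """CPA score (s) for one subject and test day: T_test - T_baseline."""
    cpa = validate_cpa(cpa)
    t_test = _pain_paired_occupancy(cpa, subject, day, compartment)
    t_baseline = _pain_paired_occupancy(cpa, subject, "baseline", compartment)
    return t_test - t_baseline


def cpa_scores_table(
    cpa: pd.DataFrame, compartment: str = "pain_paired"
) -> pd.DataFrame:
    """CPA scores for every subject x non-baseline day in the table."""
    cpa = validate_cpa(cpa)
    sub = cpa[cpa["compartment"] == compartment]
    baseline = (
        sub[sub["day"].astype(str) == "baseline"]
        .set_index("subject")["occupancy_s"]
    )
    rows = []
    for rec in sub[sub["day"].astype(str) != "baseline"].itertuples():
        if rec.subject not in baseline.index:
            raise DataError(f"subject {rec.subject!r}: missing baseline row")
        rows.append(
            (rec.subject, rec.group, str(rec.day),
             float(rec.occupancy_s - baseline[rec.subject]))
        )
    return pd.DataFrame(rows, columns=["subject", "group", "day", "cpa_score_s"])
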