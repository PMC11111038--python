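"""Risk labels from the intensification of depression-related feelings (IDF).

IDF = mean of all non-missing negative-feeling ratings (angry, fearful,
sad) on day 6, divided by the same mean over days 1-5.  A patient is
labeled 1 (at risk) when IDF strictly exceeds the case threshold; ties go
to 0.  Three standard cases are provided: thresholds 1.0, 1.2 and 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .items import NEGATIVE_FEELINGS

__all__ = ["CaseSpec", "CASES", "compute_idf", "compute_idf_all", "assign_labels"]


@dataclass(frozen=True)
class CaseSpec:
    case_id: int
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


CASES = {1: CaseSpec(1, 1.0), 2: CaseSpec(2, 1.2), 3: CaseSpec(3, 1.5)}

LABEL_DAY = 6
BASELINE_DAYS = (1, 5)


def _negative_mean(panel: pd.DataFrame, pid: str, days: tuple[int, int]) -> float:
    lo, hi = days
    sub = panel[(panel["patient_id"] == pid) & (panel["day"] >= lo) & (panel["day"] <= hi)]
    vals = sub[list(NEGATIVE_FEELINGS)].to_numpy(dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"patient {pid}: no negative-feeling ratings in days {lo}-{hi}")
    return float(vals.mean())


def compute_idf(panel: pd.DataFrame, patient_id: str) -> float:
    """IDF ratio for one patient: day-6 negative mean over day-1..5 negative mean.

    All non-missing beep x negative-item ratings pool into each mean.  The
    denominator is >= 1 (Likert minimum), so the ratio is always finite.
    """
    num = _negative_mean(panel, patient_id, (LABEL_DAY, LABEL_DAY))
    den = _negative_mean(panel, patient_id, BASELINE_DAYS)
    return num / den


def compute_idf_all(panel: pd.DataFrame) -> pd.DataFrame:
    """IDF for every patient; DataFrame with columns patient_id, idf."""
    pids = list(pd.unique(panel["patient_id"].astype(str)))
    return pd.DataFrame(
        {"patient_id": pids, "idf": [compute_idf(panel, p) for p in pids]}
    )


def assign_labels(idfs: pd.DataFrame, case: CaseSpec) -> tuple[pd.DataFrame, float]:
    """Binary labels at a case threshold: 1 iff idf > threshold (strict).

    Returns the labels frame (patient_id, idf, case_id, threshold, label)
    and the proportion labeled 1.
    """
    if idfs.empty:
        raise ValueError("no IDF values to label")
    out = idfs.copy()
    out["case_id"] = case.case_id
    out["threshold"] = case.threshold
    out["label"] = (out["idf"] > case.threshold).astype(int)
    return out, float(out["label"].mean())
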