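"""Cohort description tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .subjects import SubjectRecord


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (so 85.65 -> 85.7, not banker's 85.6)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: int, den: int) -> float:
    return round_half_up(100.0 * num / den) if den else float("nan")


def cohort_summary(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Per-group counts, percentages and outcome proportions.

    One row per group present in the cohort (patients first).  Percentages
    are rounded half-up to one decimal; ``pct_of_patients`` uses the
    patient total as denominator, outcome percentages the operated count.
    An empty cohort yields an empty table without division errors.
    """
    subjects = list(subjects)
    patients = [s for s in subjects if s.is_patient]
    rows = []
    for group in ("FLE", "TLE", "control"):
        members = [s for s in subjects if s.group == group]
        if not members:
            continue
        ages = np.array([s.age for s in members], dtype=float)
        ages = ages[~np.isnan(ages)]
        operated = [s for s in members if s.operated]
        free = [s for s in operated if s.seizure_free]
        recurred = [s for s in operated if s.seizure_recurrence]
        rows.append({
            "group": group,
            "n": len(members),
            "pct_of_patients": (_pct(len(members), len(patients))
                                if group != "control" else float("nan")),
            "age_mean": (round_half_up(float(ages.mean()))
                         if ages.size else float("nan")),
            "age_sd": (round_half_up(float(ages.std(ddof=1)))
                       if ages.size > 1 else float("nan")),
            "n_operated": len(operated),
            "n_seizure_free": len(free),
            "pct_seizure_free": _pct(len(free), len(operated)),
            "n_recurrence": len(recurred),
            "pct_recurrence": _pct(len(recurred), len(operated)),
        })
    return pd.DataFrame(rows)
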