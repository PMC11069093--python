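"""Reduce 24-hour activity profiles to the model's feature vector.

Each profile collapses to four segment statistics (morning, afternoon,
evening, overnight — hour bins matching the customary Spanish daily
timetable) plus a one-hot encoding of the walking-aid group. The default
segment statistic is the maximum smoothed hourly step count: chronic
patients move in short bursts, so a segment's peak hour captures its
representative activity level better than the sum or the mean. Both
alternatives are available behind the same interface for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocessing import DailyProfile
from .simulate import AID_GROUPS, PatientTruth

SEGMENT_NAMES = ("morning", "afternoon", "evening", "overnight")
AID_COLUMNS = ("no_walking_aid", "cane_or_walker", "wheelchair")
FEATURE_COLUMNS = (
    "morning_max",
    "afternoon_max",
    "evening_max",
    "overnight_max",
) + AID_COLUMNS
TARGET_COLUMN = "barthel_index"

_REDUCERS: dict[str, Callable[[np.ndarray], float]] = {
    "max": np.max,
    "sum": np.sum,
    "mean": np.mean,
}


@dataclass(frozen=True)
class SegmentScheme:
    """Hour-of-day bins partitioning the 24-hour day.

    Defaults: morning 07-13h, afternoon 14-19h, evening 20-23h, overnight
    00-06h (inclusive integer hour bins, so "1 PM" is the 13:00-13:59 bin).
    """

    morning: tuple[int, ...] = tuple(range(7, 14))
    afternoon: tuple[int, ...] = tuple(range(14, 20))
    evening: tuple[int, ...] = tuple(range(20, 24))
    overnight: tuple[int, ...] = tuple(range(0, 7))

    def __post_init__(self) -> None:
        all_hours = sorted(self.morning + self.afternoon + self.evening + self.overnight)
        if all_hours != list(range(24)):
            raise ValueError("segments must be disjoint and cover hours 0..23 exactly")

    def hours(self, segment: str) -> tuple[int, ...]:
        if segment not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment {segment!r}")
        return getattr(self, segment)


DEFAULT_SCHEME = SegmentScheme()


def segment_maxima(
    profile: DailyProfile,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    reducer: str = "max",
) -> dict[str, float]:
    """Reduce a profile to one statistic per day segment (default: max)."""
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}, got {reducer!r}")
    fn = _REDUCERS[reducer]
    return {
        seg: float(fn(profile.values[list(scheme.hours(seg))])) for seg in SEGMENT_NAMES
    }


def encode_aid_group(aid_group: str) -> dict[str, int]:
    """One-hot encode the walking-aid group.

    Caregiver-assisted ambulation is grouped with canes and walkers upstream
    (both provide comparable walking support, and both make the wrist device
    undercount similarly), so only three labels exist here.
    """
    if aid_group not in AID_GROUPS:
        raise ValueError(f"unknown aid group {aid_group!r}; expected one of {AID_GROUPS}")
    return {
        "no_walking_aid": int(aid_group == "none"),
        "cane_or_walker": int(aid_group == "cane_or_walker"),
        "wheelchair": int(aid_group == "wheelchair"),
    }


def build_feature_table(
    profiles: Sequence[DailyProfile],
    truths: Iterable[PatientTruth],
    scheme: SegmentScheme = DEFAULT_SCHEME,
    reducer: str = "max",
    role: str | None = None,
) -> pd.DataFrame:
    """One modelling row per profile: 4 segment features + aid one-hots + BI.

    Every profile must have a matching truth record (profiles without one are
    reported by id). ``role`` optionally tags every row (e.g. ``"test"`` for
    a production-like hold-out that must never reach training).
    """
    truth_by_id = {t.patient_id: t for t in truths}
    missing = [p.patient_id for p in profiles if p.patient_id not in truth_by_id]
    if missing:
        raise KeyError(f"no truth record for patient(s): {missing}")
    rows = []
    for p in profiles:
        t = truth_by_id[p.patient_id]
        segs = segment_maxima(p, scheme, reducer)
        row = {
            "patient_id": p.patient_id,
            f"morning_{reducer}": segs["morning"],
            f"afternoon_{reducer}": segs["afternoon"],
            f"evening_{reducer}": segs["evening"],
            f"overnight_{reducer}": segs["overnight"],
            **encode_aid_group(t.aid_group),
            "aid_group": t.aid_group,
            TARGET_COLUMN: float(t.true_bi),
        }
        if role is not None:
            row["role"] = role
        rows.append(row)
    cols = (
        ["patient_id"]
        + [f"{s}_{reducer}" for s in SEGMENT_NAMES]
        + list(AID_COLUMNS)
        + ["aid_group", TARGET_COLUMN]
        + (["role"] if role is not None else [])
    )
    return pd.DataFrame(rows, columns=cols)


def feature_matrix(table: pd.DataFrame, feature_columns: Sequence[str] = FEATURE_COLUMNS):
    """Split a modelling table into (X, y, feature_names)."""
    missing = [c for c in feature_columns if c not in table.columns]
    if missing:
        raise KeyError(f"feature table is missing columns: {missing}")
    X = table.loc[:, list(feature_columns)].to_numpy(dtype=float)
    y = table[TARGET_COLUMN].to_numpy(dtype=float)
    return X, y, list(feature_columns)
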