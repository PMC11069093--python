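"""Raw WAT streams -> per-patient mean 24-hour activity profiles.

The pipeline is: invalidate step counts wherever heart rate is missing
(a missing heart rate means the tracker was not worn properly, so the step
counter cannot be trusted), aggregate to hourly sums / hourly median heart
rate, smooth the chronological hourly series with a centred 3-wide rolling
mean, then average by hour-of-day over the 30-day window before the clinical
encounter. Patients with fewer than 14 days of usable data are excluded
rather than silently zero-filled.

Missing values are propagated, never imputed as zero: a zero would conflate
"device not worn" with "patient did not move".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["patient_id", "timestamp", "steps", "heart_rate"]
HOURLY_COLUMNS = ["patient_id", "date", "hour", "steps_sum", "hr_median"]


class InsufficientDataError(ValueError):
    """Raised when a patient has fewer usable days than the sufficiency rule."""

    def __init__(self, patient_id: str, n_days: int, min_days: int):
        self.patient_id = patient_id
        self.n_days = n_days
        self.min_days = min_days
        super().__init__(
            f"patient {patient_id!r}: {n_days} day(s) of usable data, "
            f"fewer than the required {min_days}"
        )


@dataclass(frozen=True)
class DailyProfile:
    """Mean smoothed hourly steps by hour-of-day for one patient."""

    patient_id: str
    values: np.ndarray  # shape (24,), nonnegative, finite
    n_days_used: int
    window_end: dt.date

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (24,):
            raise ValueError(f"profile must have 24 hourly values, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("profile values must be finite and nonnegative")
        object.__setattr__(self, "values", v)


def nullify_missing_hr(samples: pd.DataFrame) -> pd.DataFrame:
    """Null out step counts on samples whose heart rate is missing.

    Sample-level variant of the quality rule; :func:`aggregate_hourly`
    additionally enforces it at hourly granularity (a whole hour's step sum
    is invalidated when the hourly median heart rate is missing).
    """
    out = samples.copy()
    missing = out["heart_rate"].isna()
    if missing.any():
        out["steps"] = out["steps"].astype(float)
        out.loc[missing, "steps"] = np.nan
    return out


def aggregate_hourly(samples: pd.DataFrame, nullify_hourly: bool = True) -> pd.DataFrame:
    """Aggregate raw samples into hourly records.

    For every (patient, date, hour) with at least one sample: ``steps_sum``
    is the sum of non-null step counts and ``hr_median`` the median of
    non-null heart rates. With ``nullify_hourly`` (the default) an hour whose
    median heart rate is missing has its step sum nulled as well, so
    unmonitored hours never contribute spurious zeros or partial counts.
    """
    if samples.empty:
        return pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "date": pd.Series(dtype="datetime64[ns]"),
                "hour": pd.Series(dtype=int),
                "steps_sum": pd.Series(dtype=float),
                "hr_median": pd.Series(dtype=float),
            }
        )
    df = samples.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.normalize()
    df["hour"] = ts.dt.hour
    grouped = (
        df.groupby(["patient_id", "date", "hour"], sort=True)
        .agg(steps_sum=("steps", lambda s: s.sum(min_count=1)), hr_median=("heart_rate", "median"))
        .reset_index()
    )
    if nullify_hourly:
        bad = grouped["hr_median"].isna()
        grouped.loc[bad, "steps_sum"] = np.nan
    return grouped


def smooth_hourly(values: np.ndarray | list[float]) -> np.ndarray:
    """Centred rolling mean of width 3, skipping missing neighbours.

    ``out[i]`` is the mean of the non-null values among ``{i-1, i, i+1}``;
    at the edges only the available neighbours enter the mean (so a constant
    series is a fixed point). A position whose whole neighbourhood is null
    stays null. Length is preserved.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("smooth_hourly expects a 1-D series")
    if v.size == 0:
        return v.copy()
    valid = np.isfinite(v)
    if v.size < 3:
        # every position's neighbourhood is the whole series
        if valid.any():
            return np.full(v.size, v[valid].mean())
        return np.full(v.size, np.nan)
    filled = np.where(valid, v, 0.0)
    kernel_sum = np.convolve(filled, np.ones(3), mode="same")
    kernel_n = np.convolve(valid.astype(float), np.ones(3), mode="same")
    with np.errstate(invalid="ignore"):
        out = np.where(kernel_n > 0, kernel_sum / kernel_n, np.nan)
    return out


def build_mean_profile(
    records: pd.DataFrame,
    window_end: dt.date | pd.Timestamp,
    window_days: int = 30,
    min_days: int = 14,
) -> DailyProfile:
    """Collapse one patient's hourly records into a mean 24-hour profile.

    Restricts to the half-open ``window_days``-day window ending the day
    before ``window_end``, smooths the chronological hourly series (missing
    hours stay missing), then averages the smoothed values by hour-of-day
    over the available days. Raises :class:`InsufficientDataError` when
    fewer than ``min_days`` distinct days carry any non-null hourly data —
    the caller excludes such patients from the modelling cohort.
    """
    pids = records["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"records must belong to exactly one patient, got {list(pids)}")
    pid = str(pids[0])
    end = pd.Timestamp(window_end).normalize()
    start = end - pd.Timedelta(days=window_days)
    dates = pd.to_datetime(records["date"])
    in_window = records.loc[(dates >= start) & (dates < end)]

    # Complete chronological hourly grid over the window; hours with no
    # record at all are missing, exactly like hours nulled by the HR rule.
    grid = pd.date_range(start, end - pd.Timedelta(hours=1), freq="h")
    series = pd.Series(np.nan, index=grid)
    if not in_window.empty:
        stamp = pd.to_datetime(in_window["date"]) + pd.to_timedelta(in_window["hour"], unit="h")
        series.loc[stamp] = in_window["steps_sum"].to_numpy(dtype=float)

    n_days_used = int(series.notna().groupby(series.index.normalize()).any().sum())
    if n_days_used < min_days:
        raise InsufficientDataError(pid, n_days_used, min_days)

    smoothed = pd.Series(smooth_hourly(series.to_numpy()), index=grid)
    by_hour = smoothed.groupby(grid.hour).mean()  # NaN-aware mean over days
    values = by_hour.reindex(range(24)).to_numpy()
    # An hour-of-day with no usable data across the whole window (possible
    # only when the device was never worn at that hour) contributes no
    # activity evidence; report it as zero so the profile stays finite.
    values = np.nan_to_num(values, nan=0.0)
    return DailyProfile(pid, values, n_days_used, pd.Timestamp(end).date())


def build_profiles(
    hourly: pd.DataFrame,
    window_end_by_patient: dict[str, dt.date | pd.Timestamp],
    window_days: int = 30,
    min_days: int = 14,
) -> tuple[list[DailyProfile], list[str]]:
    """Build profiles for every patient; return (profiles, excluded_ids)."""
    profiles: list[DailyProfile] = []
    excluded: list[str] = []
    for pid, recs in hourly.groupby("patient_id", sort=True):
        if pid not in window_end_by_patient:
            raise KeyError(f"no encounter date for patient {pid!r}")
        try:
            profiles.append(
                build_mean_profile(recs, window_end_by_patient[pid], window_days, min_days)
            )
        except InsufficientDataError:
            excluded.append(str(pid))
    return profiles, excluded


def profiles_to_frame(profiles: list[DailyProfile]) -> pd.DataFrame:
    """Tabular view: patient_id, hour_0..hour_23, n_days_used."""
    rows = [
        {"patient_id": p.patient_id, **{f"hour_{h}": p.values[h] for h in range(24)},
         "n_days_used": p.n_days_used}
        for p in profiles
    ]
    cols = ["patient_id"] + [f"hour_{h}" for h in range(24)] + ["n_days_used"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_profiles(frame: pd.DataFrame, window_end: dt.date | None = None) -> list[DailyProfile]:
    """Inverse of :func:`profiles_to_frame` (window_end not round-tripped)."""
    out = []
    for _, row in frame.iterrows():
        values = np.array([row[f"hour_{h}"] for h in range(24)], dtype=float)
        out.append(
            DailyProfile(str(row["patient_id"]), values, int(row["n_days_used"]),
                         window_end or dt.date(1970, 1, 1))
        )
    return out
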