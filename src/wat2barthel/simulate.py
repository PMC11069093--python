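"""Synthetic wearable-activity-tracker (WAT) cohort generator.

Emulates the statistical structure of step-count streams recorded from
patients with complex chronic diseases wearing a wrist tracker:

* activity happens in short bursts that rarely last more than an hour and
  never span more than two consecutive clock hours;
* burst timing clusters around the customary Spanish meal hours
  (breakfast / lunch / dinner);
* burst intensity grows with the patient's Barthel Index (BI), so more
  independent patients walk more;
* wrist devices systematically undercount steps during assisted ambulation,
  so recorded counts are attenuated by walking-aid group (wheelchair
  strongest, cane/walker/caregiver intermediate, no aid none);
* heart-rate samples go missing at random (device not worn / poor contact),
  which downstream preprocessing uses to invalidate step counts;
* some patients stop wearing the device early, producing records that fail
  the >=14-of-30-day sufficiency rule.

The generator is the ground-truth source for every downstream stage: it
returns both the raw sample stream and the per-patient truth (BI, walking-aid
group, encounter date).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AID_GROUPS = ("wheelchair", "cane_or_walker", "none")
BI_CLASSES = ("A", "B", "C")

#: Inclusive BI grid per dependence class, in the instrument's steps of 5.
#: A = total dependence (BI <= 20), B = severe (20 < BI <= 60),
#: C = moderate/mild dependence or independent (BI > 60).
BI_GRID_BY_CLASS = {
    "A": tuple(range(0, 21, 5)),
    "B": tuple(range(25, 61, 5)),
    "C": tuple(range(65, 101, 5)),
}


def _default_class_mix() -> dict[str, float]:
    # 90-patient pilot cohort: 10 class A, 40 class B, 40 class C.
    return {"A": 1 / 9, "B": 4 / 9, "C": 4 / 9}


def _default_aid_mix() -> dict[str, dict[str, float]]:
    # Chosen so the implied marginals approximate the reported aid usage
    # (~17% wheelchair, ~26% cane/walker/caregiver, ~58% none) while making
    # aid need decrease with independence.
    return {
        "A": {"wheelchair": 0.70, "cane_or_walker": 0.25, "none": 0.05},
        "B": {"wheelchair": 0.20, "cane_or_walker": 0.45, "none": 0.35},
        "C": {"wheelchair": 0.02, "cane_or_walker": 0.13, "none": 0.85},
    }


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for one synthetic cohort.

    Rates are per day, amplitudes are expected steps per burst-hour for a
    mid-range BI; the realised per-patient amplitude scales linearly with BI
    so activity is monotone in functional independence within each class.
    """

    n_patients: int = 90
    days_recorded: int = 30
    seed: int = 0
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    aid_mix_given_class: dict[str, dict[str, float]] = field(default_factory=_default_aid_mix)
    burst_rate_by_class: dict[str, float] = field(
        default_factory=lambda: {"A": 2.0, "B": 5.0, "C": 8.0}
    )
    burst_amplitude_by_class: dict[str, float] = field(
        default_factory=lambda: {"A": 40.0, "B": 150.0, "C": 350.0}
    )
    meal_anchor_hours: tuple[int, ...] = (9, 14, 21)
    missing_hr_prob: float = 0.05
    dropout_prob: float = 0.10
    attenuation_by_aid: dict[str, float] = field(
        default_factory=lambda: {"wheelchair": 0.15, "cane_or_walker": 0.6, "none": 1.0}
    )
    sampling_minutes: int = 1
    start_date: dt.date = dt.date(2022, 3, 1)
    burst_two_hour_prob: float = 0.25
    burst_hour_sd: float = 1.2

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.days_recorded <= 0:
            raise ValueError(f"days_recorded must be positive, got {self.days_recorded}")
        if not (60 % self.sampling_minutes == 0 and self.sampling_minutes >= 1):
            raise ValueError("sampling_minutes must be a positive divisor of 60")
        for name, probs in [("class_mix", self.class_mix)] + [
            (f"aid_mix_given_class[{c}]", m) for c, m in self.aid_mix_given_class.items()
        ]:
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} proportions must be nonnegative")
        if set(self.class_mix) != set(BI_CLASSES):
            raise ValueError(f"class_mix keys must be {BI_CLASSES}")
        for c in BI_CLASSES:
            if set(self.aid_mix_given_class[c]) != set(AID_GROUPS):
                raise ValueError(f"aid_mix_given_class[{c}] keys must be {AID_GROUPS}")
        for name, d in [
            ("burst_rate_by_class", self.burst_rate_by_class),
            ("burst_amplitude_by_class", self.burst_amplitude_by_class),
        ]:
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} values must be nonnegative")
        if not all(0 <= h <= 23 for h in self.meal_anchor_hours):
            raise ValueError("meal_anchor_hours must lie in 0..23")
        for name, p in [
            ("missing_hr_prob", self.missing_hr_prob),
            ("dropout_prob", self.dropout_prob),
            ("burst_two_hour_prob", self.burst_two_hour_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    true_bi: int
    aid_group: str
    encounter_date: dt.date
    bi_class: str

    def __post_init__(self) -> None:
        if not (0 <= self.true_bi <= 100 and self.true_bi % 5 == 0):
            raise ValueError(f"true_bi must be a multiple of 5 in 0..100, got {self.true_bi}")
        if self.aid_group not in AID_GROUPS:
            raise ValueError(f"unknown aid_group {self.aid_group!r}")


def _simulate_patient_minutes(
    rng: np.random.Generator,
    config: SimConfig,
    bi: int,
    rate: float,
    amplitude: float,
    n_days: int,
) -> np.ndarray:
    """Per-minute true step counts over ``n_days`` days (length n_days*1440)."""
    steps = np.zeros(n_days * 1440, dtype=np.int64)
    anchors = np.asarray(config.meal_anchor_hours)
    # Expected steps in one burst-hour, scaled by independence: a BI-100
    # patient is 3x as intense as a BI-0 patient of the same class.
    amp = amplitude * (0.5 + bi / 100.0)
    n_bursts = rng.poisson(rate, size=n_days)
    for day in np.flatnonzero(n_bursts):
        for _ in range(int(n_bursts[day])):
            anchor = anchors[rng.integers(len(anchors))]
            hour = int(np.clip(round(rng.normal(anchor, config.burst_hour_sd)), 0, 23))
            two_hours = hour < 23 and rng.random() < config.burst_two_hour_prob
            dur_hours = 2 if two_hours else 1
            total = rng.poisson(amp * dur_hours)
            if total == 0:
                continue
            # Burst is confined to clock hours [hour, hour + dur_hours):
            # it never spans more than two consecutive hours.
            m0 = int(rng.integers(0, 60))
            max_len = dur_hours * 60 - m0
            stretch = int(rng.integers(1, max_len + 1))
            start = (day * 24 + hour) * 60 + m0
            alloc = rng.multinomial(total, np.full(stretch, 1.0 / stretch))
            steps[start : start + stretch] += alloc
    return steps


def generate_cohort(config: SimConfig) -> tuple[list[PatientTruth], pd.DataFrame]:
    """Simulate a cohort of WAT streams plus per-patient ground truth.

    Returns ``(truths, samples)`` where ``samples`` is a long-format frame
    with columns ``patient_id, timestamp, steps, heart_rate`` at the
    configured sampling interval. ``steps`` holds the *recorded* (aid-group
    attenuated) counts; heart rate is fully observed here — use
    :func:`inject_missingness` to add the missing-at-random heart-rate gaps.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths: list[PatientTruth] = []
    frames: list[pd.DataFrame] = []
    classes = list(BI_CLASSES)
    class_p = np.array([config.class_mix[c] for c in classes])
    encounter = config.start_date + dt.timedelta(days=config.days_recorded)
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        cls = classes[rng.choice(len(classes), p=class_p)]
        bi = int(rng.choice(BI_GRID_BY_CLASS[cls]))
        aid_p = np.array([config.aid_mix_given_class[cls][g] for g in AID_GROUPS])
        aid = AID_GROUPS[rng.choice(len(AID_GROUPS), p=aid_p)]
        truths.append(PatientTruth(pid, bi, aid, encounter, cls))

        n_days = config.days_recorded
        if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
            # Early dropout: keep a uniformly chosen prefix of the record.
            n_days = int(rng.integers(1, config.days_recorded + 1))
        minute_steps = _simulate_patient_minutes(
            rng,
            config,
            bi,
            config.burst_rate_by_class[cls],
            config.burst_amplitude_by_class[cls],
            n_days,
        )
        p_keep = config.attenuation_by_aid[aid]
        recorded = (
            rng.binomial(minute_steps, p_keep) if p_keep < 1.0 else minute_steps
        )
        hr_base = rng.normal(72.0, 5.0)
        hr = hr_base + 8.0 * (minute_steps > 0) + rng.normal(0.0, 2.0, minute_steps.size)
        hr = np.clip(np.round(hr), 40, 180)

        step = config.sampling_minutes
        if step > 1:
            recorded = recorded.reshape(-1, step).sum(axis=1)
            hr = hr.reshape(-1, step).mean(axis=1).round()
        ts = pd.date_range(
            start=pd.Timestamp(config.start_date),
            periods=recorded.size,
            freq=f"{step}min",
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "timestamp": ts,
                    "steps": recorded.astype("int64"),
                    "heart_rate": hr,
                }
            )
        )
    if frames:
        samples = pd.concat(frames, ignore_index=True)
    else:
        samples = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns]"),
                "steps": pd.Series(dtype="int64"),
                "heart_rate": pd.Series(dtype=float),
            }
        )
    return truths, samples


def inject_missingness(
    samples: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Set heart rate to missing independently per sample.

    Step counts are untouched: invalidating steps recorded while heart rate
    is missing is the preprocessing stage's job, not the generator's. The
    sample count and ordering are preserved.
    """
    p = config.missing_hr_prob
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"missing_hr_prob must be in [0, 1], got {p}")
    if samples.empty:
        return samples.copy()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = samples.copy()
    mask = rng.random(len(out)) < p
    out.loc[mask, "heart_rate"] = np.nan
    return out


def truncate_patients(
    samples: pd.DataFrame, patient_ids: list[str], keep_days: int
) -> pd.DataFrame:
    """Keep only the first ``keep_days`` calendar days for the given patients.

    Utility for engineering under-recorded patients that must fail the
    14-day sufficiency rule downstream.
    """
    if keep_days < 0:
        raise ValueError("keep_days must be >= 0")
    targeted = samples["patient_id"].isin(patient_ids)
    if not targeted.any():
        return samples.copy()
    dates = samples["timestamp"].dt.normalize()
    cutoffs = dates[targeted].groupby(samples["patient_id"][targeted]).min() + pd.Timedelta(
        days=keep_days
    )
    keep = ~targeted | (dates < samples["patient_id"].map(cutoffs))
    return samples.loc[keep].reset_index(drop=True)
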