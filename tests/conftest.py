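import numpy as np
import pandas as pd
import pytest

from wat2barthel import features as ft
from wat2barthel import preprocessing as pp
from wat2barthel.simulate import SimConfig, generate_cohort, inject_missingness


@pytest.fixture(scope="session")
def small_cohort():
    """10 patients x 20 days, no dropout, with heart-rate gaps injected."""
    cfg = SimConfig(n_patients=10, days_recorded=20, seed=42, dropout_prob=0.0,
                    missing_hr_prob=0.05)
    truths, samples = generate_cohort(cfg)
    samples = inject_missingness(samples, cfg)
    return cfg, truths, samples


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    cfg, truths, samples = small_cohort
    hourly = pp.aggregate_hourly(samples)
    profiles, excluded = pp.build_profiles(
        hourly, {t.patient_id: t.encounter_date for t in truths}
    )
    assert not excluded
    return ft.build_feature_table(profiles, truths)


def make_table(n_by_group: dict[str, int], seed: int = 0) -> pd.DataFrame:
    """Feature-table skeleton with given walking-aid group sizes."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group, n in n_by_group.items():
        for _ in range(n):
            rows.append(
                {
                    "patient_id": f"P{i:04d}",
                    "morning_max": rng.uniform(0, 200),
                    "afternoon_max": rng.uniform(0, 200),
                    "evening_max": rng.uniform(0, 200),
                    "overnight_max": rng.uniform(0, 50),
                    "no_walking_aid": int(group == "none"),
                    "cane_or_walker": int(group == "cane_or_walker"),
                    "wheelchair": int(group == "wheelchair"),
                    "aid_group": group,
                    "barthel_index": float(5 * rng.integers(0, 21)),
                }
            )
            i += 1
    return pd.DataFrame(rows)
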