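import numpy as np
import pandas as pd
import pytest

from cgmed.clae import CLAEConfig, train_clae
from cgmed.pipeline import preprocess_logs
from cgmed.preprocessing import chronological_split
from cgmed.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort with no injected gaps/artifacts (known-clean streams)."""
    cfg = SyntheticConfig(n_subjects=4, days_per_subject=14, seed=11,
                          gap_rate=0.0, artifact_rate=0.0)
    logs, truth = simulate_cohort(cfg)
    return cfg, logs, truth


@pytest.fixture(scope="session")
def split_windows(clean_cohort):
    """Retained windows from the clean cohort, chronologically split."""
    _, logs, _ = clean_cohort
    retained, tally = preprocess_logs(logs)
    spec, train, test = chronological_split(retained)
    return spec, train, test, tally


@pytest.fixture(scope="session")
def mini_model(split_windows):
    """A briefly trained autoencoder shared across embedding tests."""
    spec, train, _, _ = split_windows
    model, history = train_clae(train, CLAEConfig(epochs=8, seed=3), spec)
    return model, history


def make_toy_log():
    """Hand-constructed 10-meal event log with known exclusion violations.

    Meals are spaced 400 minutes apart except two overlapping pairs
    (80 minutes apart); a six-reading CGM gap falls in the pre-window of one
    overlap-pair member (so the missing-data violation shares a window with
    an overlap violation); one clean meal has a bolus at +75 minutes.
    Exactly five windows survive the exclusion rules: five distinct windows
    carry at least one violation.
    """
    from cgmed.synthetic import MealEventLog

    n_days_min = 6000
    grid = np.arange(0, n_days_min, 5)
    rng = np.random.default_rng(99)
    glucose = 140 + 10 * np.sin(grid / 200) + rng.normal(0, 2, len(grid))

    base_times = [400, 800, 880, 1600, 2000, 2400, 2480, 3200, 3600, 4000]
    # pairs (800, 880) and (2400, 2480) overlap; the gap at [700, 725] sits
    # inside the pre-window of the meal at 800 only; 3600 gets the late bolus
    meals = pd.DataFrame({
        "timestamp_min": base_times,
        "carbs_g": np.full(10, 45.0),
        "meal_type": ["lunch"] * 10,
    })
    gap_start_idx = 700 // 5
    glucose[gap_start_idx:gap_start_idx + 6] = np.nan      # six missing readings
    # the second member of each overlap pair gets no bolus of its own, so
    # no window is incidentally flagged for a neighbour's meal-time bolus
    bolus_times = [t for t in base_times if t not in (880, 2480)]
    boluses = pd.DataFrame({
        "timestamp_min": bolus_times + [3600 + 75],
        "units": [3.0] * len(bolus_times) + [1.5],
    })
    empty_grid = pd.DataFrame({"timestamp_min": grid})
    return MealEventLog(
        subject_id="TOY", cohort="2018",
        cgm=pd.DataFrame({"timestamp_min": grid, "glucose": glucose}),
        boluses=boluses,
        basal=pd.DataFrame({"timestamp_min": [0], "rate_u_hr": [1.0]}),
        meals=meals,
        heart_rate=empty_grid.assign(bpm=75.0),
        steps=empty_grid.assign(count=0),
    )


@pytest.fixture()
def toy_log():
    return make_toy_log()
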