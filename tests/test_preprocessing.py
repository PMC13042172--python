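"""Window extraction, exclusion rules, mediator aggregation, and the split."""

import numpy as np
import pandas as pd
import pytest

from cgmed import HORIZONS
from cgmed.preprocessing import (aggregate_mediator, apply_exclusions,
                                 chronological_split, extract_windows,
                                 interpolate_gaps, read_windows,
                                 standardize_pre_matrices, windows_to_table,
                                 write_windows)
from cgmed.synthetic import ValidationError, _snap


def _series(values):
    return pd.DataFrame({"timestamp_min": np.arange(len(values)) * 5,
                         "glucose": values})


class TestInterpolation:
    def test_fills_short_run_linearly(self):
        vals = [100.0] + [np.nan] * 5 + [130.0]
        out, report = interpolate_gaps(_series(vals))
        np.testing.assert_allclose(out.glucose,
                                   [100, 105, 110, 115, 120, 125, 130])
        assert report.filled_runs == [(1, 5)]
        assert report.unfilled_runs == []

    def test_six_missing_left_alone(self):
        vals = [100.0] + [np.nan] * 6 + [130.0]
        out, report = interpolate_gaps(_series(vals))
        assert out.glucose.isna().sum() == 6
        assert report.unfilled_runs == [(1, 6)]

    def test_boundary_run_not_filled(self):
        vals = [np.nan, np.nan, 100.0, 105.0]
        out, report = interpolate_gaps(_series(vals))
        assert out.glucose.isna().sum() == 2
        assert report.unfilled_runs == [(0, 2)]

    def test_identity_when_complete(self):
        vals = list(100.0 + np.arange(10))
        out, report = interpolate_gaps(_series(vals))
        np.testing.assert_array_equal(out.glucose, vals)
        assert not report.filled_runs and not report.unfilled_runs

    def test_rejects_off_grid_timestamps(self):
        bad = pd.DataFrame({"timestamp_min": [0, 7, 10], "glucose": [1., 2., 3.]})
        with pytest.raises(ValidationError):
            interpolate_gaps(bad)


def test_snap_to_grid_ties_round_down():
    np.testing.assert_array_equal(_snap(np.array([1000, 1002, 1003, 1002.5])),
                                  [1000, 1000, 1005, 1000])


class TestExtraction:
    def test_pre_matrix_covers_expected_grid(self, toy_log):
        windows = extract_windows(toy_log)
        w = next(w for w in windows if w.meal_time == 400)
        assert w.pre_matrix.shape == (24, 5)
        grid_glucose = toy_log.cgm.set_index("timestamp_min").glucose
        np.testing.assert_allclose(
            w.pre_matrix[:, 0], grid_glucose.loc[280:395].to_numpy())
        assert w.G0 == grid_glucose.loc[400]
        assert w.post_glucose[0] == w.G0

    def test_delta_g_matches_raw_series(self, toy_log):
        for w in extract_windows(toy_log):
            for t in HORIZONS:
                if not np.isnan(w.delta_g[t]):
                    assert w.delta_g[t] == pytest.approx(
                        w.post_glucose[t // 5] - w.G0)
        # the implied excursion at the meal time itself is exactly zero
        assert all(w.post_glucose[0] - w.G0 == 0.0
                   for w in extract_windows(toy_log)
                   if not np.isnan(w.G0))

    def test_meal_near_log_edge_flagged_incomplete(self, toy_log):
        toy_log.meals.loc[len(toy_log.meals)] = {"timestamp_min": 100,
                                                 "carbs_g": 30.0,
                                                 "meal_type": "snack"}
        windows = extract_windows(toy_log)
        w = next(w for w in windows if w.meal_time == 100)
        assert "incomplete" in w.exclusion_flags


class TestExclusions:
    def test_toy_log_retains_exactly_five(self, toy_log):
        windows = extract_windows(toy_log)
        retained, tally = apply_exclusions(windows)
        assert len(retained) == 5
        assert tally["overlap"] == 4
        assert tally["missing"] == 1
        assert tally["late_bolus"] == 1
        assert tally["retained"] == 5
        assert tally["retained"] + tally["excluded"] == len(windows)
        assert sorted(w.meal_time for w in retained) == \
            [400, 1600, 2000, 3200, 4000]

    def test_clean_windows_fully_retained(self, split_windows):
        *_, tally = split_windows
        assert tally["excluded"] == 0

    def test_bolus_at_plus_sixty_is_mediator_not_late(self):
        boluses = pd.DataFrame({"timestamp_min": [1060], "units": [2.0]})
        assert aggregate_mediator(1000, boluses) == 2.0


class TestMediatorAggregation:
    BOLUSES = pd.DataFrame({"timestamp_min": [970, 1045], "units": [2.0, 1.5]})

    def test_sums_inside_closed_window(self):
        assert aggregate_mediator(1000, self.BOLUSES) == pytest.approx(3.5)

    def test_boundary_exclusion(self):
        b = pd.DataFrame({"timestamp_min": [879, 880, 1060, 1061],
                          "units": [1.0, 1.0, 1.0, 1.0]})
        assert aggregate_mediator(1000, b) == pytest.approx(2.0)

    def test_no_boluses_gives_zero(self):
        empty = pd.DataFrame({"timestamp_min": [], "units": []})
        assert aggregate_mediator(1000, empty) == 0.0

    def test_negative_bolus_rejected(self):
        bad = pd.DataFrame({"timestamp_min": [990], "units": [-1.0]})
        with pytest.raises(ValidationError):
            aggregate_mediator(1000, bad)


class TestSplit:
    @staticmethod
    def _dummy_windows(n_days):
        from cgmed.preprocessing import MealWindow
        rng = np.random.default_rng(0)
        return [MealWindow(subject_id="A", cohort="2018", meal_type="lunch",
                           meal_time=day * 1440 + 600,
                           pre_matrix=rng.normal(size=(24, 5)),
                           Z=50.0, M=2.0, G0=120.0,
                           delta_g={t: 0.0 for t in HORIZONS},
                           post_glucose=np.zeros(43))
                for day in range(n_days)]

    def test_twenty_days_split_thirteen_seven(self):
        spec, train, test = chronological_split(self._dummy_windows(20))
        train_days = sorted({w.meal_time // 1440 for w in train})
        test_days = sorted({w.meal_time // 1440 for w in test})
        assert train_days == list(range(13))
        assert test_days == list(range(13, 20))

    def test_temporal_consistency(self, split_windows):
        _, train, test, _ = split_windows
        last_train = {}
        first_test = {}
        for w in train:
            last_train[w.subject_id] = max(last_train.get(w.subject_id, 0),
                                           w.meal_time)
        for w in test:
            first_test[w.subject_id] = min(
                first_test.get(w.subject_id, np.inf), w.meal_time)
        for subj in first_test:
            assert last_train[subj] < first_test[subj]

    def test_training_standardization_is_unit_scale(self, split_windows):
        spec, train, test, _ = split_windows
        std = standardize_pre_matrices(train, spec)
        means = std.mean(axis=(0, 1))
        sds = std.std(axis=(0, 1))
        varying = spec.channel_sd != 1.0  # constant channels are left as-is
        np.testing.assert_allclose(means[varying], 0.0, atol=1e-10)
        np.testing.assert_allclose(sds[varying], 1.0, atol=1e-10)
        test_means = standardize_pre_matrices(test, spec).mean(axis=(0, 1))
        assert np.abs(test_means[varying]).max() > 1e-3

    def test_single_day_subject_rejected(self, split_windows):
        _, train, _, _ = split_windows
        one_day = [w for w in train
                   if w.subject_id == train[0].subject_id
                   and w.meal_time // 1440 == train[0].meal_time // 1440]
        with pytest.raises(ValidationError, match=one_day[0].subject_id):
            chronological_split(one_day)


def _fresh(log):
    import copy
    return copy.deepcopy(log)


def test_windows_table_and_io_round_trip(tmp_path, split_windows):
    _, train, _, _ = split_windows
    sample = train[:7]
    write_windows(sample, tmp_path)
    table = windows_to_table(sample)
    assert len(table) == len(sample)
    assert set(f"delta_g_{t}" for t in HORIZONS) <= set(table.columns)
    back = read_windows(tmp_path)
    for w, b in zip(sample, back):
        assert (w.subject_id, w.meal_type, w.meal_time) == \
            (b.subject_id, b.meal_type, b.meal_time)
        np.testing.assert_allclose(w.pre_matrix, b.pre_matrix)
        np.testing.assert_allclose(w.post_glucose, b.post_glucose)
        assert w.delta_g == pytest.approx(b.delta_g)
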