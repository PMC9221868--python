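"""Sequence preparation: interpolation, resampling, windowing, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaforecast import build_windowed_dataset, min_max_normalise, resample_monthly, series_to_frame, sliding_window
from vaforecast.prep import (
    DAYS_PER_MONTH,
    TimedValue,
    encode_timesteps_as_features,
    grouped_train_val_test,
    impute_missing,
    interpolate_linear,
)


class TestInterpolateLinear:
    def test_midpoint(self):
        assert interpolate_linear(TimedValue(0, 0), TimedValue(2, 1), 1) == pytest.approx(0.5)

    def test_hand_evaluated_case(self):
        assert interpolate_linear(TimedValue(0, 0.2), TimedValue(3, 0.5), 1) == pytest.approx(0.3)

    def test_constant_endpoints(self):
        assert interpolate_linear(TimedValue(0, 0.7), TimedValue(5, 0.7), 2.3) == pytest.approx(0.7)

    def test_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            interpolate_linear(TimedValue(0, 0), TimedValue(2, 1), 2.5)
        with pytest.raises(ValueError):
            interpolate_linear(TimedValue(0, 0), TimedValue(2, 1), 0.0)

    def test_agrees_with_library_interpolation_oracle(self, rng):
        """1000 random valid triples against numpy's interp to 1e-12."""
        for _ in range(1000):
            t1, dt_, y1, y2 = rng.uniform(0, 10), rng.uniform(0.1, 5), rng.normal(), rng.normal()
            t2 = t1 + dt_
            t = rng.uniform(t1 + 1e-6, t2 - 1e-6)
            ours = interpolate_linear(TimedValue(t1, y1), TimedValue(t2, y2), t)
            oracle = np.interp(t, [t1, t2], [y1, y2])
            assert abs(ours - oracle) < 1e-12


class TestSlidingWindow:
    def test_five_visits_k3_gives_three_windows(self):
        result = sliding_window(["v1", "v2", "v3", "v4", "v5"], 3)
        assert [list(w) for w in result.windows] == [
            ["v1", "v2", "v3"],
            ["v2", "v3", "v4"],
            ["v3", "v4", "v5"],
        ]

    def test_k_equals_n_returns_whole_series(self):
        result = sliding_window([1, 2, 3], 3)
        assert len(result) == 1 and list(result.windows[0]) == [1, 2, 3]

    def test_k_above_n_returns_empty(self):
        assert len(sliding_window([1, 2, 3, 4, 5], 6)) == 0

    def test_count_formula(self):
        assert len(sliding_window(list(range(7)), 2)) == 6

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            sliding_window([1, 2], 0)

    @settings(deadline=None, max_examples=200)
    @given(n=st.integers(0, 20), k=st.integers(1, 22))
    def test_matches_bruteforce_slice_enumeration(self, n, k):
        ts = list(range(n))
        result = sliding_window(ts, k)
        brute = [ts[i : i + k] for i in range(n) if len(ts[i : i + k]) == k]
        assert [list(w) for w in result.windows] == brute


def _frame(t, va, feat=None):
    data = {"t": np.asarray(t, float), "va": np.asarray(va, float),
            "treated": np.zeros(len(t)), "observed": np.ones(len(t))}
    if feat is not None:
        data["C0_avg_thickness"] = np.asarray(feat, float)
    f = pd.DataFrame(data)
    f.attrs["eye_id"] = "P1_L"
    f.attrs["patient_id"] = "P1"
    return f


class TestResampleMonthly:
    def test_already_regular_is_identity(self):
        f = _frame([0, 1, 2], [0.2, 0.3, 0.4], [0.25, 0.26, 0.27])
        out = resample_monthly(f)
        pd.testing.assert_frame_equal(out, f, check_like=True)

    def test_gap_interpolated_at_midpoint(self):
        f = _frame([0, 2], [0.2, 0.4])
        out = resample_monthly(f)
        assert list(out["t"]) == [0.0, 1.0, 2.0]
        assert out["va"].iloc[1] == pytest.approx(0.3)
        assert out["observed"].iloc[1] == 0.0

    def test_collision_keeps_later_visit(self):
        f = _frame([0.0, 0.5, 2.0], [0.2, 0.9, 0.4])
        out = resample_monthly(f)
        assert out["va"].iloc[0] == pytest.approx(0.9)

    def test_idempotent(self):
        f = _frame([0, 1.7, 3.9], [0.2, 0.5, 0.3])
        once = resample_monthly(f)
        twice = resample_monthly(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_equally_spaced(self, small_cohort):
        _, cohort, _ = small_cohort
        for series in cohort[:5]:
            out = resample_monthly(series_to_frame(series))
            assert np.allclose(np.diff(out["t"]), 1.0)

    def test_interpolated_month_gets_no_treatment(self):
        f = _frame([0, 2], [0.2, 0.4])
        f.loc[0, "treated"] = 1.0
        out = resample_monthly(f)
        assert out["treated"].iloc[1] == 0.0


class TestTimestepEncoding:
    def test_first_visit_has_time_zero(self, small_cohort):
        _, cohort, _ = small_cohort
        out = encode_timesteps_as_features(series_to_frame(cohort[0]))
        assert out["t"].iloc[0] == 0.0

    def test_sixty_one_days_is_two_months(self):
        from vaforecast.records import EyeSeries, VisitRecord
        import datetime as dt

        s = EyeSeries("P1", "L", [
            VisitRecord(visit_date=dt.date(2020, 1, 1), va=0.5),
            VisitRecord(visit_date=dt.date(2020, 3, 2), va=0.6),
        ])
        f = encode_timesteps_as_features(series_to_frame(s))
        assert f["t"].iloc[1] == pytest.approx(61 / DAYS_PER_MONTH)
        assert f["t"].iloc[1] == pytest.approx(2.0, abs=0.01)

    def test_composes_with_resampling(self):
        f = _frame([0, 1.8, 3.6], [0.2, 0.5, 0.3])
        out = encode_timesteps_as_features(resample_monthly(f))
        assert list(out["t"]) == [0.0, 1.0, 2.0, 3.0]


class TestMinMaxNormalise:
    def test_basic_scaling(self):
        (scaled,), _ = min_max_normalise(np.array([[0.0], [5.0], [10.0]]))
        assert np.allclose(scaled.ravel(), [0, 0.5, 1])

    def test_constant_feature_maps_to_zero(self):
        (scaled,), _ = min_max_normalise(np.array([[3.0], [3.0], [3.0]]))
        assert np.allclose(scaled, 0.0)

    def test_test_values_may_leave_unit_interval(self):
        (tr, te), _ = min_max_normalise(np.array([[0.0], [10.0]]), np.array([[20.0]]))
        assert te[0, 0] == pytest.approx(2.0)

    def test_preserves_ordering(self, rng):
        x = rng.normal(size=(30, 4))
        (scaled,), _ = min_max_normalise(x)
        for j in range(4):
            assert np.array_equal(np.argsort(scaled[:, j]), np.argsort(x[:, j]))


class TestImputeMissing:
    def test_interior_gap_linear(self):
        f = _frame([0, 1, 2], [0.2, np.nan, 0.4])
        out = impute_missing(f)
        assert out["va"].iloc[1] == pytest.approx(0.3)

    def test_leading_missing_takes_nearest(self):
        f = _frame([0, 1, 2], [np.nan, 0.5, 0.6])
        out = impute_missing(f)
        assert list(out["va"]) == pytest.approx([0.5, 0.5, 0.6])

    def test_no_missing_is_identity(self):
        f = _frame([0, 1, 2], [0.1, 0.2, 0.3])
        pd.testing.assert_frame_equal(impute_missing(f), f)

    def test_all_missing_left_flagged(self):
        f = _frame([0, 1], [np.nan, np.nan])
        out = impute_missing(f)
        assert np.isnan(out["va"]).all()
        assert out.attrs["all_missing_features"] == ["va"]


class TestBuildWindowedDataset:
    def test_window_count_five_regular_visits(self):
        f = _frame([0, 1, 2, 3, 4], [0.5, 0.6, 0.7, 0.6, 0.5])
        ds = build_windowed_dataset([f], "resampled", 2, "va_only")
        assert len(ds) == 3  # k = 3 over n = 5
        assert ds.inputs.shape == (3, 2, 2)

    def test_short_series_yields_no_windows(self):
        f = _frame([0, 1, 2], [0.5, 0.6, 0.7])
        ds = build_windowed_dataset([f], "resampled", 3, "va_only")
        assert len(ds) == 0

    def test_total_count_matches_sum_formula(self, small_cohort):
        _, cohort, _ = small_cohort
        frames = [series_to_frame(s) for s in cohort]
        for k_in in (1, 2, 3):
            k = k_in + 1
            ds = build_windowed_dataset(frames, "timesteps", k_in, "oct_numeric")
            expected = sum(max(0, len(f) - k + 1) for f in frames)
            assert len(ds) == expected

    def test_targets_in_unit_interval(self, small_cohort):
        _, cohort, _ = small_cohort
        frames = [series_to_frame(s) for s in cohort]
        ds = build_windowed_dataset(frames, "resampled", 2, "oct_numeric")
        assert np.all(ds.targets >= 0) and np.all(ds.targets <= 1)

    def test_timesteps_encoding_carries_target_time(self):
        f = _frame([0, 1.5, 4.0], [0.5, 0.6, 0.7])
        ds = build_windowed_dataset([f], "timesteps", 2, "va_only")
        names = ds.feature_names
        assert "t" in names and "t_target" in names
        t_target = ds.inputs[0, :, names.index("t_target")]
        assert np.allclose(t_target, 4.0)

    def test_save_load_round_trip(self, small_cohort, tmp_path):
        _, cohort, _ = small_cohort
        frames = [series_to_frame(s) for s in cohort]
        ds = build_windowed_dataset(frames, "resampled", 2, "va_only")
        ds.save(tmp_path / "ds")
        back = ds.load(tmp_path / "ds")
        assert np.allclose(back.inputs, ds.inputs)
        assert np.allclose(back.targets, ds.targets)
        assert list(back.groups) == list(ds.groups)


def test_grouped_split_never_straddles_groups(rng):
    groups = np.repeat([f"P{i}" for i in range(20)], 4)
    tr, va, te = grouped_train_val_test(groups, (0.6, 0.3, 0.1), seed=3)
    sets = [set(groups[idx]) for idx in (tr, va, te)]
    assert sets[0] & sets[1] == set()
    assert sets[0] & sets[2] == set()
    assert sets[1] & sets[2] == set()
    assert len(tr) + len(va) + len(te) == len(groups)
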