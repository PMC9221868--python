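"""Forecasting models and the metric suite."""

import numpy as np
import pytest

from vaforecast import (
    RecurrentNetConfig,
    build_windowed_dataset,
    compute_metrics,
    fit_recurrent,
    fit_shallow,
    run_experiment,
    series_to_frame,
)
from vaforecast.forecast import grouped_folds
from vaforecast.prep import WindowedDataset


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([0.2, 0.5, 0.9], [0.2, 0.5, 0.9])
        assert rep.mse == 0 and rep.mae == 0 and rep.rmse == 0
        assert rep.r2 == pytest.approx(1.0)

    def test_constant_mean_prediction_r2_zero(self):
        a = np.array([0.2, 0.4, 0.6])
        rep = compute_metrics(a, np.full(3, a.mean()))
        assert rep.r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        rep = compute_metrics([0.5, 0.5], [0.4, 0.6])
        assert rep.mse == pytest.approx(0.01)
        assert rep.mae == pytest.approx(0.1)
        assert rep.rmse == pytest.approx(0.1)
        assert rep.rmspe == pytest.approx(0.2)

    def test_matches_bruteforce_definitions(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            a = rng.uniform(0.05, 1.0, size=n)
            p = rng.uniform(0.0, 1.0, size=n)
            rep = compute_metrics(a, p)
            assert rep.mse == pytest.approx(np.mean((a - p) ** 2), abs=1e-12)
            assert rep.mae == pytest.approx(np.mean(np.abs(a - p)), abs=1e-12)
            assert rep.rmse == pytest.approx(np.sqrt(rep.mse), abs=1e-9)
            assert rep.rmspe == pytest.approx(np.sqrt(np.mean(((a - p) / a) ** 2)), abs=1e-12)
            assert rep.r2 == pytest.approx(
                1 - np.sum((a - p) ** 2) / np.sum((a - a.mean()) ** 2), abs=1e-12
            )

    def test_rmspe_guard_on_near_zero_actuals(self):
        rep = compute_metrics([1e-6, 1e-9], [0.1, 0.1])
        assert not rep.rmspe_defined
        assert np.isnan(rep.rmspe)


def _toy_dataset(rng, n_eyes=30, linear=True):
    inputs, targets, groups = [], [], []
    for e in range(n_eyes):
        for _ in range(3):
            x = rng.uniform(0, 1, size=(2, 3))
            y = 0.2 + 0.5 * x[-1, 0] if linear else rng.uniform(0, 1)
            inputs.append(x)
            targets.append(np.clip(y, 0, 1))
            groups.append(f"P{e}")
    return WindowedDataset(
        np.stack(inputs),
        np.array(targets),
        np.array(groups, dtype=object),
        np.array(groups, dtype=object),
        ["f1", "f2", "f3"],
        "resampled",
        3,
    )


class TestFitShallow:
    def test_noiseless_linear_target_exact_fit(self, rng):
        ds = _toy_dataset(rng, linear=True)
        rep = fit_shallow(ds, "linear")
        assert rep.r2 >= 0.999

    def test_null_target_low_r2(self, rng):
        ds = _toy_dataset(rng, linear=False)
        rep = fit_shallow(ds, "linear")
        assert rep.r2 <= 0.1

    def test_ten_folds_on_ample_groups(self, rng):
        ds = _toy_dataset(rng, n_eyes=30)
        rep = fit_shallow(ds, "linear", n_folds=10)
        assert len(rep.fold_scores) == 10

    def test_fold_count_reduced_with_few_groups(self, rng):
        ds = _toy_dataset(rng, n_eyes=4)
        rep = fit_shallow(ds, "linear", n_folds=10)
        assert len(rep.fold_scores) == 4

    def test_invariant_to_sample_order(self, rng):
        ds = _toy_dataset(rng)
        perm = np.random.default_rng(0).permutation(len(ds))
        shuffled = WindowedDataset(
            ds.inputs[perm], ds.targets[perm], ds.groups[perm], ds.eye_ids[perm],
            ds.feature_names, ds.encoding, ds.k,
        )
        a = fit_shallow(ds, "gbm", seed=1)
        b = fit_shallow(shuffled, "gbm", seed=1)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)

    def test_folds_never_split_a_patient(self, rng):
        groups = np.repeat([f"P{i}" for i in range(17)], 3)
        folds = grouped_folds(groups, 10, seed=0)
        for fold in folds:
            inside = set(groups[fold])
            outside = set(groups[np.setdiff1d(np.arange(len(groups)), fold)])
            assert inside & outside == set()


@pytest.fixture(scope="module")
def quiet_dataset(quiet_cohort):
    _, cohort, _ = quiet_cohort
    frames = [series_to_frame(s) for s in cohort]
    return build_windowed_dataset(frames, "resampled", 2, "va_only")


class TestFitRecurrent:
    def test_predictions_within_unit_interval(self, quiet_dataset):
        cfg = RecurrentNetConfig(nn_type="gru", hidden_units=8, epochs_max=5, seed=0)
        rep, model = fit_recurrent(quiet_dataset, cfg)
        preds = model.predict(quiet_dataset.inputs)
        assert np.all(preds > 0) and np.all(preds < 1)

    def test_learns_low_noise_va_law(self, quiet_dataset):
        cfg = RecurrentNetConfig(nn_type="gru", hidden_units=32, epochs_max=200, seed=0)
        rep, _ = fit_recurrent(quiet_dataset, cfg)
        assert rep.r2 >= 0.8

    def test_same_seed_identical_metrics(self, quiet_dataset):
        cfg = RecurrentNetConfig(nn_type="simple", hidden_units=8, epochs_max=8, seed=3)
        rep_a, _ = fit_recurrent(quiet_dataset, cfg)
        cfg_b = RecurrentNetConfig(nn_type="simple", hidden_units=8, epochs_max=8, seed=3)
        rep_b, _ = fit_recurrent(quiet_dataset, cfg_b)
        assert rep_a.mse == rep_b.mse
        assert rep_a.r2 == rep_b.r2

    def test_zero_timesteps_rejected(self):
        from vaforecast.forecast import RecurrentNetRegressor

        with pytest.raises(ValueError):
            RecurrentNetRegressor(epochs_max=1).fit(np.zeros((10, 0, 3)), np.zeros(10))


class TestRunExperiment:
    def test_grid_layout(self, quiet_cohort):
        _, cohort, _ = quiet_cohort
        grid = run_experiment(
            cohort,
            experiments=("va_only",),
            encodings=("resampled", "timesteps"),
            visit_counts=(1, 2),
            models=("linear", "gbm"),
        )
        assert len(grid) == 2 * 2 * 2
        assert set(grid.columns) >= {"experiment", "model", "encoding", "n_input_visits", "r2", "rmspe"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_experiment([], experiments=("va_only",))

    def test_missing_embeddings_named(self, quiet_cohort):
        _, cohort, _ = quiet_cohort
        with pytest.raises(ValueError, match=cohort[0].eye_id):
            run_experiment(cohort, experiments=("oct_plus_images",))

    def test_permuted_treatment_degrades_linear_fit(self):
        """Treatment carries real signal: permuting the flag hurts CV R²."""
        from vaforecast import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=60, seed=21, va_noise_sd=0.005, treatment_effect=0.15)
        cohort, _ = generate_cohort(cfg)
        frames = [series_to_frame(s) for s in cohort]
        ds = build_windowed_dataset(frames, "timesteps", 1, "va_only")
        base = fit_shallow(ds, "linear")
        rng = np.random.default_rng(0)
        treated_col = ds.feature_names.index("treated")
        permuted = ds.inputs.copy()
        flat = permuted[:, :, treated_col].ravel()
        rng.shuffle(flat)
        permuted[:, :, treated_col] = flat.reshape(permuted[:, :, treated_col].shape)
        ds_perm = WindowedDataset(
            permuted, ds.targets, ds.groups, ds.eye_ids, ds.feature_names, ds.encoding, ds.k
        )
        perm = fit_shallow(ds_perm, "linear")
        assert perm.r2 < base.r2
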