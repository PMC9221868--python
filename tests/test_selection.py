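"""Correlation coefficients and multivariate feature selection."""

import numpy as np
import pytest
from scipy import stats

from vaforecast import lasso_select, pearson, rfe_select, spearman, univariate_report
from vaforecast.selection import zero_variance_filter


class TestPearson:
    def test_perfect_positive(self, rng):
        x = rng.normal(size=20)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self, rng):
        x = rng.normal(size=20)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 9])
        dx, dy = x - x.mean(), y - y.mean()
        expected = np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2))
        assert pearson(x, y) == pytest.approx(expected, abs=1e-15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=15)
        assert spearman(x, x**3) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, rng):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_rank_difference_enumeration(self):
        # ranks of x: 1,2,3; ranks of y: 3,1,2 -> d = (-2, 1, 1)
        x, y = [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]
        expected = 1 - 6 * (4 + 1 + 1) / (3 * 8)
        assert spearman(x, y) == pytest.approx(expected)

    def test_monotone_invariance(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)


def test_correlations_agree_with_scipy_on_tie_free_pairs(rng):
    """1000 random continuous pairs against the library implementations."""
    for _ in range(1000):
        n = rng.integers(4, 30)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


class TestUnivariateReport:
    def test_22_rows_and_sign_structure(self, quiet_cohort):
        _, cohort, truth = quiet_cohort
        report = univariate_report(cohort)
        assert len(report) == 22
        row = report[report.feature == "C0_avg_thickness"].iloc[0]
        # thicker fovea -> worse acuity under a positive thickness-VA slope
        assert truth.thickness_va_slope > 0
        assert row.r < 0
        assert row.rho < 0

    def test_independent_noise_feature_near_zero(self, rng):
        """|r| of white noise against VA obeys the null ~2/sqrt(n) bound."""
        n = 2000
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert abs(pearson(x, y)) <= 2 / np.sqrt(n) * 2  # 4 sigma


class TestZeroVariance:
    def test_constant_across_all_series_dropped(self):
        a = np.array([[1.0, 5.0], [1.0, 6.0]])
        b = np.array([[1.0, 2.0], [1.0, 9.0]])
        assert list(zero_variance_filter([a, b])) == [1]

    def test_constant_in_one_series_only_kept(self):
        a = np.array([[1.0, 5.0], [1.0, 6.0]])
        b = np.array([[1.0, 2.0], [3.0, 9.0]])
        assert list(zero_variance_filter([a, b])) == [0, 1]

    def test_no_constants_identity(self, rng):
        blocks = [rng.normal(size=(4, 5)) for _ in range(3)]
        assert list(zero_variance_filter(blocks)) == list(range(5))


class TestRfe:
    def test_planted_signal_ranked_first(self, rng):
        x = rng.normal(size=(120, 5))
        y = 3.0 * x[:, 2] + rng.normal(0, 0.05, size=120)
        result = rfe_select(x, y, cv=5, seed=0)
        assert 2 in result["selected"]
        assert result["ranking"][2] == 1

    def test_two_feature_elimination_matches_exhaustive_oracle(self, rng):
        from sklearn.ensemble import GradientBoostingRegressor
        from sklearn.metrics import r2_score

        x = rng.normal(size=(80, 2))
        y = 2.0 * x[:, 1] + rng.normal(0, 0.1, size=80)
        result = rfe_select(x, y, n_features_to_select=1, seed=0)
        # oracle: fit each single feature and keep the better one
        scores = []
        for j in range(2):
            est = GradientBoostingRegressor(random_state=0).fit(x[:, [j]], y)
            scores.append(r2_score(y, est.predict(x[:, [j]])))
        assert result["selected"] == [int(np.argmax(scores))]

    def test_selected_subset_of_inputs(self, rng):
        x = rng.normal(size=(60, 4))
        y = x[:, 0] + rng.normal(0, 0.1, size=60)
        result = rfe_select(x, y, cv=3, seed=0)
        assert set(result["selected"]) <= {0, 1, 2, 3}

    def test_estimator_without_importances_rejected(self, rng):
        from sklearn.neighbors import KNeighborsRegressor

        x = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            rfe_select(x, y, estimator=KNeighborsRegressor(), cv=3)


class TestLasso:
    def test_pure_noise_features_zeroed(self, rng):
        x = rng.normal(size=(100, 6))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.05, size=100)
        result = lasso_select(x, y, cv=5, seed=0)
        assert 0 in result["selected"]
        weights = np.array(result["weights"])
        assert np.sum(np.abs(weights[1:]) > 0.05) == 0

    def test_zero_penalty_equals_ols(self, rng):
        from sklearn.linear_model import LinearRegression

        x = rng.normal(size=(50, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, size=50)
        result = lasso_select(x, y, cv=0)
        ols = LinearRegression().fit(x, y)
        assert np.allclose(result["weights"], ols.coef_)

    def test_retained_set_shrinks_with_penalty(self, rng):
        from sklearn.linear_model import Lasso

        x = rng.normal(size=(80, 5))
        y = x @ np.array([2.0, 1.0, 0.5, 0.0, 0.0]) + rng.normal(0, 0.1, size=80)
        sizes = []
        for alpha in (0.001, 0.05, 0.5, 2.0):
            n_kept = np.sum(Lasso(alpha=alpha, max_iter=50_000).fit(x, y).coef_ != 0)
            sizes.append(n_kept)
        assert sizes == sorted(sizes, reverse=True)


def test_selection_reproducible_under_seed(rng):
    x = rng.normal(size=(60, 4))
    y = x[:, 1] + rng.normal(0, 0.2, size=60)
    a = rfe_select(x, y, cv=3, seed=5)
    b = rfe_select(x, y, cv=3, seed=5)
    assert a == b
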