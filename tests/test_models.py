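"""The six model families against closed-form and simulation oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import strokepred as sp
from strokepred.models import (
    ConvergenceError,
    DegenerateComparisonError,
    _f_from_rss,
    _prepare,
)

from .oracles import pinv_ols, ridge_closed_form, soft_threshold_oracle


def make_regression(n=40, p=6, active=(0, 2), beta=3.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    b = np.zeros(p)
    b[list(active)] = beta
    y = X @ b + noise * rng.normal(size=n)
    return X, y


class TestFitOLS:
    def test_perfect_fit_zero_rss(self):
        X, y = make_regression(noise=0.0)
        fit = sp.fit_ols(X, y)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_six_point_bivariate_matches_normal_equations(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 2.0], [5.0, 5.0], [6.0, 3.0]])
        y = np.array([1.0, 2.0, 2.5, 3.5, 4.0, 5.5])
        fit = sp.fit_ols(X, y)
        Xs, yc, _, _ = _prepare(X, y)
        coef_oracle, rss_oracle = pinv_ols(Xs, yc, intercept=False)
        np.testing.assert_allclose(fit.coefficients, coef_oracle, atol=1e-10)
        assert fit.rss == pytest.approx(rss_oracle, abs=1e-10)

    def test_duplicated_column_minimum_norm_with_warning(self):
        X, y = make_regression(n=30, p=4)
        Xd = np.column_stack([X, X[:, 1]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_dup = sp.fit_ols(Xd, y)
        fit = sp.fit_ols(X, y)
        np.testing.assert_allclose(
            sp.predict(fit_dup, Xd), sp.predict(fit, X), atol=1e-8
        )

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_ols(np.empty((0, 3)), np.empty(0))


class TestFTest:
    def test_redundant_predictor_gives_f_zero_p_one(self):
        X, y = make_regression(n=30, p=3, noise=0.3)
        Xd = np.column_stack([X, X[:, 0]])  # exactly redundant extra column
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sp.fit_ols(Xd, y)
        reduced = sp.fit_ols(Xd, y, selected=[0, 1, 2])
        res = sp.f_test_nested(full, reduced)
        assert res.f_stat == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_hand_arithmetic_on_the_formula(self):
        # RSS_r=10, RSS_f=8, dp=1, df_f=20 -> F = (2/1)/(8/20) = 5.0
        res = _f_from_rss(10.0, 8.0, 1, 20, scale=10.0)
        assert res.f_stat == pytest.approx(5.0)
        assert res.p_value == pytest.approx(stats.f.sf(5.0, 1, 20))

    def test_degenerate_comparison_rejected(self):
        with pytest.raises(DegenerateComparisonError):
            _f_from_rss(1.0, 1.0, 0, 10, scale=1.0)

    def test_null_pvalues_uniform(self):
        # adding a pure-noise predictor: p-values must be U(0,1)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(2000):
            n = 25
            X = rng.normal(size=(n, 3))
            y = X[:, 0] + rng.normal(size=n)
            full = sp.fit_ols(X, y)
            reduced = sp.fit_ols(X, y, selected=[0, 1])
            pvals.append(sp.f_test_nested(full, reduced).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestHierarchicalSelect:
    def test_high_snr_predictor_retained_both_directions(self):
        X, y = make_regression(n=60, p=10, active=(4,), beta=10.0, noise=1.0, seed=1)
        for direction in ("backward", "forward"):
            fit = sp.hierarchical_select(X, y, direction)
            assert 4 in fit.selected

    def test_all_noise_yields_intercept_only_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        for direction in ("backward", "forward"):
            fit = sp.hierarchical_select(X, y, direction, alpha=1e-6)
            assert fit.selected == []
            np.testing.assert_allclose(sp.predict(fit, X), y.mean())

    def test_selection_sequence_matches_manual_trace(self):
        """Backward pass replayed step by step with statsmodels F-tests."""
        sm = pytest.importorskip("statsmodels.api")
        X, y = make_regression(n=35, p=5, active=(1, 3), beta=2.0, noise=1.0, seed=9)
        Xs, yc, _, _ = _prepare(X, y)
        selected = [0, 1, 2, 3, 4]
        while True:
            changed = False
            for j in sorted(selected, reverse=True):
                full = sm.OLS(yc, sm.add_constant(Xs[:, selected])).fit()
                trial = [i for i in selected if i != j]
                red = sm.OLS(yc, sm.add_constant(Xs[:, trial]) if trial else
                             np.ones((len(yc), 1))).fit()
                f_p = full.compare_f_test(red)[1]
                if f_p > 0.05:
                    selected = trial
                    changed = True
            if not changed:
                break
        fit = sp.hierarchical_select(X, y, "backward")
        assert fit.selected == selected

    def test_alpha_out_of_range_rejected(self):
        X, y = make_regression()
        with pytest.raises(ValueError):
            sp.hierarchical_select(X, y, "backward", alpha=1.5)


class TestStepwiseSelect:
    def test_cap_enforced_with_lower_index_tie_break(self):
        # two identical predictors: exactly one retained, the lower index
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        y = 5 * x + 0.1 * rng.normal(size=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sp.stepwise_select(X, y, "forward", max_predictors=1)
        assert fit.selected == [0]

    def test_active_set_recovered_at_high_snr(self):
        hits = 0
        for seed in range(200):
            X, y = make_regression(n=60, p=8, active=(1, 4, 6), beta=4.0,
                                   noise=1.0, seed=seed)
            fit = sp.stepwise_select(X, y, "forward", max_predictors=8)
            hits += {1, 4, 6} <= set(fit.selected)
        assert hits / 200 >= 0.95

    def test_null_forward_selects_little(self):
        sizes = []
        rng = np.random.default_rng(11)
        for _ in range(500):
            X = rng.normal(size=(40, 8))
            y = rng.normal(size=40)
            fit = sp.stepwise_select(X, y, "forward", alpha=0.05)
            sizes.append(len(fit.selected))
        assert np.mean(sizes) <= 1.5

    def test_backward_stops_when_all_significant(self):
        X, y = make_regression(n=60, p=6, active=(0, 3), beta=5.0, noise=1.0, seed=5)
        fit = sp.stepwise_select(X, y, "backward")
        assert {0, 3} <= set(fit.selected)
        assert len(fit.selected) <= 3


class TestRidge:
    def test_zero_penalty_equals_ols(self):
        X, y = make_regression()
        np.testing.assert_allclose(
            sp.fit_ridge(X, y, 0.0).coefficients,
            sp.fit_ols(X, y).coefficients,
            atol=1e-10,
        )

    def test_infinite_penalty_kills_coefficients(self):
        X, y = make_regression()
        fit = sp.fit_ridge(X, y, 1e12)
        assert np.abs(fit.coefficients).max() < 1e-6
        # intercept survives: prediction tends to the training mean
        np.testing.assert_allclose(sp.predict(fit, X), y.mean(), atol=1e-4)

    def test_matches_closed_form_oracle(self):
        X, y = make_regression(n=5, p=3, noise=1.0, seed=7)
        fit = sp.fit_ridge(X, y, 2.0)
        Xs, yc, _, _ = _prepare(X, y)
        np.testing.assert_allclose(
            fit.coefficients, ridge_closed_form(Xs, yc, 2.0), atol=1e-10
        )

    def test_coefficient_norm_nonincreasing_in_penalty(self):
        X, y = make_regression(n=30, p=5, seed=13)
        norms = [
            np.linalg.norm(sp.fit_ridge(X, y, lam).coefficients)
            for lam in 10.0 ** np.linspace(-4, 4, 20)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_negative_penalty_rejected(self):
        X, y = make_regression()
        with pytest.raises(ValueError):
            sp.fit_ridge(X, y, -1.0)

    def test_matches_sklearn_ridge(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X, y = make_regression(n=40, p=6, seed=47)
        for lam in (0.5, 5.0, 50.0):
            fit = sp.fit_ridge(X, y, lam)
            Xs, yc, _, _ = _prepare(X, y)
            ref = sklearn_lm.Ridge(alpha=lam, fit_intercept=False).fit(Xs, yc)
            np.testing.assert_allclose(fit.coefficients, ref.coef_, atol=1e-10)


class TestLasso:
    def test_lambda_max_shuts_off_every_coefficient(self):
        X, y = make_regression(n=30, p=6, seed=17)
        lam_max = sp.lasso_lambda_max(X, y)
        for lam in (lam_max, lam_max * 1.5):
            fit = sp.fit_lasso(X, y, lam)
            np.testing.assert_array_equal(fit.coefficients, 0.0)

    def test_orthonormal_design_soft_threshold_closed_form(self):
        rng = np.random.default_rng(19)
        q, _ = np.linalg.qr(rng.normal(size=(60, 5)))
        Xs = q * np.sqrt(60)  # orthonormal columns scaled to unit variance
        yc = rng.normal(size=60)
        yc -= yc.mean()
        lam = 0.05
        fit_coef = None
        from strokepred.models import _lasso_cd

        fit_coef = _lasso_cd(Xs, yc, lam, 1e-10, 50_000)
        ols = Xs.T @ yc / (Xs**2).sum(axis=0)
        col_nrm = (Xs**2).sum(axis=0) / 60
        expected = soft_threshold_oracle(ols * col_nrm, lam) / col_nrm
        np.testing.assert_allclose(fit_coef, expected, atol=1e-8)

    def test_duplicated_strong_predictor_collinearity(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        y = 4 * x + 0.5 * rng.normal(size=50)
        fit = sp.fit_lasso(X, y, sp.lasso_lambda_max(X, y) * 0.3)
        assert len({0, 1} & set(fit.selected)) <= 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lam_frac=st.floats(0.01, 0.9))
    def test_kkt_conditions_hold_on_random_instances(self, seed, lam_frac):
        X, y = make_regression(n=30, p=8, seed=seed, noise=1.0)
        lam = sp.lasso_lambda_max(X, y) * lam_frac
        fit = sp.fit_lasso(X, y, lam)
        assert sp.lasso_kkt_violation(X, y, fit) < 1e-6

    def test_active_set_nonincreasing_in_penalty(self):
        X, y = make_regression(n=40, p=8, active=(0, 2, 5), seed=29)
        lam_max = sp.lasso_lambda_max(X, y)
        sizes = [
            len(sp.fit_lasso(X, y, lam_max * f).selected)
            for f in (0.01, 0.05, 0.2, 0.5, 1.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_matches_sklearn_lasso(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X, y = make_regression(n=40, p=6, seed=53)
        lam = sp.lasso_lambda_max(X, y) * 0.2
        fit = sp.fit_lasso(X, y, lam)
        Xs, yc, _, _ = _prepare(X, y)
        ref = sklearn_lm.Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                               max_iter=100_000).fit(Xs, yc)
        np.testing.assert_allclose(fit.coefficients, ref.coef_, atol=1e-7)

    def test_nonconvergence_carries_last_iterate(self):
        X, y = make_regression(n=30, p=6, seed=31)
        with pytest.raises(ConvergenceError) as exc:
            sp.fit_lasso(X, y, sp.lasso_lambda_max(X, y) * 0.01, tol=1e-14, max_iter=2)
        assert exc.value.coefficients.shape == (6,)


class TestPredict:
    def test_in_sample_identity(self):
        X, y = make_regression(noise=0.0)
        fit = sp.fit_ols(X, y)
        np.testing.assert_allclose(sp.predict(fit, X), y, atol=1e-10)

    def test_column_means_predict_intercept(self):
        X, y = make_regression(seed=37)
        fit = sp.fit_ridge(X, y, 1.0)
        pred = sp.predict(fit, X.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_matches_oracle_matrix_product(self):
        X, y = make_regression(n=20, p=3, seed=41)
        fit = sp.fit_ols(X, y)
        X_new = np.random.default_rng(43).normal(size=(4, 3))
        Xs_new = (X_new - fit.scaler.mean) / fit.scaler.scale
        expected = fit.intercept + Xs_new @ fit.coefficients
        np.testing.assert_allclose(sp.predict(fit, X_new), expected, atol=1e-12)

    def test_column_mismatch_rejected(self):
        X, y = make_regression(p=4)
        fit = sp.fit_ols(X, y)
        with pytest.raises(ValueError):
            sp.predict(fit, X[:, :3])


class TestAffineInvariance:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_selection_invariant_to_predictor_rescaling(self, seed):
        X, y = make_regression(n=50, p=6, active=(1, 4), beta=2.0, seed=seed)
        scales = np.array([1e-3, 1.0, 50.0, 2.0, 1e3, 0.1])
        shifts = np.array([10.0, -5.0, 0.0, 100.0, -2.0, 1.0])
        X2 = X * scales + shifts
        for select in (
            lambda X_, y_: sp.hierarchical_select(X_, y_, "backward").selected,
            lambda X_, y_: sp.stepwise_select(X_, y_, "forward").selected,
        ):
            assert select(X, y) == select(X2, y)


class TestModelFitSerialization:
    def test_json_round_trip(self, tmp_path):
        X, y = make_regression()
        fit = sp.fit_lasso(X, y, sp.lasso_lambda_max(X, y) * 0.2)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = sp.ModelFit.from_json(path)
        assert back.family == "lasso"
        assert back.selected == fit.selected
        np.testing.assert_allclose(back.coefficients, fit.coefficients)
        np.testing.assert_allclose(sp.predict(back, X), sp.predict(fit, X))
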