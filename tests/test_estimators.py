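"""Tests of the five effect estimators and the adaptive-lasso machinery."""

import numpy as np
import pytest

from caldose import (
    AdaptiveLasso,
    CausalLinearRegressor,
    DesignMatrix,
    PixelwiseRegressor,
    adaptive_weights_from_pilot,
    build_adjustment_set,
    build_design_matrix,
    compute_adaptive_weights,
    fit_adaptive_lasso,
    fit_cal,
    fit_pixelwise,
    fit_pixelwise_cal,
)


# ---------------------------------------------------------------------------
# Pixel-wise (voxel-based) regression


class TestPixelwise:
    def test_exact_univariate_slope(self, rng):
        dose = rng.normal(5, 2, size=(50, 4, 4))
        y = 2.0 * dose[:, 1, 2] + 1.0  # noise-free single-pixel response
        reg = PixelwiseRegressor(grid_shape=(4, 4)).fit(dose, y)
        assert reg.theta_hat_[1, 2] == pytest.approx(2.0, abs=1e-10)

    def test_degenerate_pixel_flagged(self, rng):
        dose = rng.normal(size=(30, 2, 2))
        dose[:, 0, 0] = 7.0  # constant column
        y = rng.normal(size=30)
        reg = PixelwiseRegressor(grid_shape=(2, 2)).fit(dose, y)
        assert reg.degenerate_mask_[0, 0]
        assert reg.theta_hat_[0, 0] == 0.0

    def test_slope_matches_cov_var_oracle(self, small_cohort):
        est = fit_pixelwise(small_cohort, "planned")
        d = small_cohort.D_plan
        y = small_cohort.Y
        for (i, j) in [(0, 0), (1, 3), (2, 2)]:
            x = d[:, i, j]
            oracle = np.cov(x, y, bias=True)[0, 1] / np.var(x)
            assert est.theta_hat[i, j] == pytest.approx(oracle, rel=1e-9)

    def test_requires_three_observations(self, rng):
        with pytest.raises(ValueError):
            PixelwiseRegressor().fit(rng.normal(size=(2, 5)), rng.normal(size=2))


# ---------------------------------------------------------------------------
# Causal regression without sparsity


class TestCausalNoSparsity:
    def test_exact_recovery_noise_free(self, rng, small_cohort):
        # linear outcome in dose and plan parameters, no noise: OLS is exact
        theta = rng.normal(size=16)
        X = np.column_stack([small_cohort.D_del.reshape(120, -1),
                             small_cohort.plan_params()])
        y = X @ np.concatenate([theta, [0.5, -0.3, 2.0]]) + 1.0
        reg = CausalLinearRegressor(grid_shape=(4, 4)).fit(X, y)
        assert reg.converged_
        np.testing.assert_allclose(reg.theta_hat_.ravel(), theta, atol=1e-8)

    def test_matches_qr_reference(self, rng):
        X = rng.normal(size=(60, 12))
        y = rng.normal(size=60)
        reg = CausalLinearRegressor().fit(X, y)
        Z = np.column_stack([np.ones(60), X])
        Q, R = np.linalg.qr(Z)
        ref = np.linalg.solve(R, Q.T @ y)
        assert reg.intercept_ == pytest.approx(ref[0], abs=1e-9)
        np.testing.assert_allclose(reg.coef_, ref[1:], atol=1e-9)

    def test_underdetermined_declared_nonconverged(self, rng):
        X = rng.normal(size=(15, 19))  # p >= n
        reg = CausalLinearRegressor().fit(X, rng.normal(size=15))
        assert not reg.converged_
        assert reg.theta_hat_ is None

    def test_rank_deficiency_declared_nonconverged(self, rng):
        X = rng.normal(size=(50, 8))
        X[:, 3] = X[:, 2]  # exact collinearity: no silent pseudo-inverse
        reg = CausalLinearRegressor().fit(X, rng.normal(size=50))
        assert not reg.converged_


# ---------------------------------------------------------------------------
# Adjustment sets


class TestAdjustmentSet:
    def test_variant_b_cardinality(self):
        labels = build_adjustment_set((0, 0), (10, 10), "b")
        assert len(labels) == 99 + 3
        assert {"V_O", "M_O", "V_T"} <= set(labels)

    def test_variant_a_contains_confounder(self):
        labels = build_adjustment_set((0, 0), (10, 10), "a")
        assert len(labels) == 99 + 1
        assert "C" in labels

    def test_own_pixel_excluded(self):
        labels = build_adjustment_set((3, 4), (10, 10))
        assert "D_3_4" not in labels

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            build_adjustment_set((10, 0), (10, 10))


# ---------------------------------------------------------------------------
# Adaptive weight arithmetic


class TestAdaptiveWeights:
    @pytest.mark.parametrize(
        "beta, gamma, expected",
        [([2.0, -0.5], 1.0, [0.5, 2.0]),
         ([2.0], 2.0, [0.25]),
         ([4.0, -2.0, 1.0], 1.0, [0.25, 0.5, 1.0])],
    )
    def test_weight_arithmetic(self, beta, gamma, expected):
        np.testing.assert_allclose(
            adaptive_weights_from_pilot(np.array(beta), gamma), expected)

    def test_near_zero_pilot_excluded(self):
        w = adaptive_weights_from_pilot(np.array([1.0, 1e-12]))
        assert w[0] == 1.0 and np.isinf(w[1])

    def test_forced_in_columns_have_zero_weight(self, rng):
        X = rng.normal(size=(80, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=80)
        mask = np.ones(8, dtype=int)
        mask[[2, 5]] = 0
        design = DesignMatrix(X=X, feature_labels=[f"x{i}" for i in range(8)],
                              y=y, penalty_mask=mask)
        w, alpha_ridge = compute_adaptive_weights(design, cv_folds=10, random_state=0)
        assert w[2] == 0.0 and w[5] == 0.0
        assert np.all(w[[0, 1, 3, 4, 6, 7]] > 0)
        assert alpha_ridge > 0


# ---------------------------------------------------------------------------
# Adaptive lasso solver


def weighted_lasso_objective(X, y, coef, intercept, weights, lam):
    """Sum-of-squares + lam * sum_j w_j |b_j| (the estimation objective)."""
    resid = y - intercept - X @ coef
    pen = np.sum(weights[np.isfinite(weights)] * np.abs(coef[np.isfinite(weights)]))
    return np.sum(resid**2) + lam * pen


def coordinate_descent_weighted_lasso(X, y, weights, lam, n_iter=3000):
    """Independent brute-force solver of the weighted lasso with intercept
    (cyclic coordinate descent with exact soft-thresholding updates)."""
    n, p = X.shape
    coef = np.zeros(p)
    intercept = y.mean()
    col_ss = (X**2).sum(axis=0)
    for _ in range(n_iter):
        resid = y - intercept - X @ coef
        intercept += resid.mean()
        for j in range(p):
            resid = y - intercept - X @ coef
            rho = X[:, j] @ resid + col_ss[j] * coef[j]
            thresh = lam * weights[j] / 2.0
            coef[j] = np.sign(rho) * max(abs(rho) - thresh, 0.0) / col_ss[j]
    return coef, intercept


class TestAdaptiveLasso:
    def _make_problem(self, rng, n=80, p=15, sparsity=4, noise=0.5):
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:sparsity] = rng.normal(3, 1, size=sparsity)
        y = X @ beta + 1.5 + noise * rng.normal(size=n)
        return X, y, beta

    def test_zero_penalty_equals_ols(self, rng):
        X, y, _ = self._make_problem(rng, n=100, p=20)
        model = AdaptiveLasso(alpha_lasso=0.0, random_state=0).fit(X, y)
        Z = np.column_stack([np.ones(100), X])
        ref, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(model.coef_, ref[1:], atol=1e-6)
        assert model.intercept_ == pytest.approx(ref[0], abs=1e-6)

    def test_saturating_penalty_zeroes_penalized_block(self, rng):
        X, y, _ = self._make_problem(rng)
        model = AdaptiveLasso(alpha_lasso=1e9, penalty_free=[0, 1],
                              random_state=0).fit(X, y)
        assert np.all(model.coef_[2:] == 0.0)
        # forced-in columns equal OLS on just those columns
        Z = np.column_stack([np.ones(80), X[:, :2]])
        ref, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(model.coef_[:2], ref[1:], atol=1e-8)

    def test_cv_fit_beats_random_perturbations(self, rng):
        # the returned coefficients minimize the weighted-lasso objective
        X, y, _ = self._make_problem(rng)
        model = AdaptiveLasso(cv=10, penalty_free=[14], random_state=0).fit(X, y)
        lam = model.lambda_lasso_
        w = model.weights_.copy()
        finite = np.isfinite(w)
        obj_hat = weighted_lasso_objective(X[:, finite], y, model.coef_[finite],
                                           model.intercept_, w[finite], lam)
        full = np.concatenate([[model.intercept_], model.coef_[finite]])
        for _ in range(1000):
            pert = full + rng.normal(0, 0.03, size=full.size)
            obj = weighted_lasso_objective(X[:, finite], y, pert[1:], pert[0],
                                           w[finite], lam)
            assert obj >= obj_hat - 1e-9

    def test_matches_independent_coordinate_descent(self, rng):
        # rescaling route vs direct weighted coordinate descent, n=50 p=10
        X = rng.normal(size=(50, 10))
        beta = np.concatenate([rng.normal(2, 1, size=3), np.zeros(7)])
        y = X @ beta + 0.5 + 0.3 * rng.normal(size=50)
        weights = rng.uniform(0.5, 3.0, size=10)
        alpha = 0.05  # sklearn scale; objective scale lam = 2 n alpha
        model = AdaptiveLasso(weights=weights, alpha_lasso=alpha,
                              random_state=0).fit(X, y)
        ref_coef, ref_int = coordinate_descent_weighted_lasso(
            X, y, weights, lam=2 * 50 * alpha)
        np.testing.assert_allclose(model.coef_, ref_coef, atol=1e-6)
        assert model.intercept_ == pytest.approx(ref_int, abs=1e-6)

    def test_deterministic_given_seed(self, rng):
        X, y, _ = self._make_problem(rng)
        a = AdaptiveLasso(random_state=7).fit(X, y)
        b = AdaptiveLasso(random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.alpha_lasso_ == b.alpha_lasso_

    def test_excluded_columns_get_zero_coefficient(self, rng):
        X, y, _ = self._make_problem(rng)
        w = np.ones(15)
        w[4] = np.inf  # excluded by infinite weight
        model = AdaptiveLasso(weights=w, alpha_lasso=0.01, random_state=0).fit(X, y)
        assert model.coef_[4] == 0.0

    def test_cv_fold_too_small_rejected(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        with pytest.raises(ValueError):
            AdaptiveLasso(cv=10).fit(X, y)

    def test_fit_adaptive_lasso_wrapper(self, rng):
        X, y, _ = self._make_problem(rng, n=60, p=8)
        mask = np.ones(8, dtype=int)
        mask[0] = 0
        design = DesignMatrix(X=X, feature_labels=[f"x{i}" for i in range(8)],
                              y=y, penalty_mask=mask)
        w, _ = compute_adaptive_weights(design, random_state=0)
        fit = fit_adaptive_lasso(design, w, random_state=0)
        assert fit.beta_hat.shape == (8,)
        assert np.all(fit.weights[mask == 0] == 0)
        assert 0 in fit.support  # forced-in column always in the model


# ---------------------------------------------------------------------------
# CAL and pixel-wise CAL on cohorts


class TestCAL:
    def test_plan_parameters_always_included(self, small_cohort):
        design = build_design_matrix(small_cohort)
        from caldose import CausalAdaptiveLasso

        model = CausalAdaptiveLasso(grid_shape=(4, 4), random_state=0)
        model.fit(design.X, design.y)
        assert np.all(model.lasso_.weights_[-3:] == 0)
        assert np.all(model.lasso_.coef_[-3:] != 0)

    def test_finite_under_extreme_collinearity(self, small_config):
        from caldose import simulate_cohort

        cfg = small_config.replace(sigma2_ud=3e-12, m_gp=3e-12,
                                   sigma2_gp=3e-12, sigma2_l=3e-12)
        est = fit_cal(simulate_cohort(cfg), random_state=0)
        assert np.all(np.isfinite(est.theta_hat))

    def test_sparse_estimates_on_null_pixels(self, default_cohort):
        est = fit_cal(default_cohort, random_state=0)
        zero = default_cohort.estimands.theta == 0
        assert (est.theta_hat[zero] == 0).mean() > 0.5

    def test_pixelwise_cal_forces_own_pixel(self, rng):
        from caldose import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(nx=3, ny=3, n_obs=60, seed=5,
                               tumor_exclusion_radius=0)
        cohort = simulate_cohort(cfg)
        est = fit_pixelwise_cal(cohort, random_state=0)
        assert est.diagnostics["n_fits"] == 9
        assert np.all(np.isfinite(est.theta_hat))
        # fit (1,1): forced-in set is exactly {D_11, V_O, M_O, V_T}
        from caldose import PixelwiseCausalAdaptiveLasso, build_design_matrix

        design = build_design_matrix(cohort)
        model = PixelwiseCausalAdaptiveLasso(grid_shape=(3, 3), random_state=0)
        model.fit(design.X, design.y)
        w = model.pixel_fits_[(1, 1)].weights
        forced_cols = {1 * 3 + 1, 9, 10, 11}
        assert set(np.flatnonzero(w == 0)) == forced_cols


# ---------------------------------------------------------------------------
# Property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True)
@given(
    beta=st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20),
    gamma=st.floats(min_value=0.5, max_value=3.0),
    signs=st.lists(st.sampled_from([-1.0, 1.0]), min_size=20, max_size=20),
)
def test_weight_arithmetic_property(beta, gamma, signs):
    """w_j = 1/|beta*_j|^gamma holds for any pilot sign and magnitude."""
    b = np.array(beta) * np.array(signs[: len(beta)])
    w = adaptive_weights_from_pilot(b, gamma)
    np.testing.assert_allclose(w, 1.0 / np.abs(b) ** gamma, rtol=1e-12)
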