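"""Adjustment, density-ratio instance weights, and balance diagnostics."""

import numpy as np
import pytest
from scipy import stats as st

from deconfound.confounds import (
    adjust_features,
    apply_adjustment,
    compute_instance_weights,
    estimate_conditional_density,
    estimate_target_density,
    fit_adjustment,
    weighted_standardized_difference,
)
from deconfound.data import augment_confounds
from deconfound.exceptions import SingularMatrixError, ValidationError
from deconfound.gp import predict_gp


class TestAdjustment:
    def test_beta_matches_per_feature_ols_oracle(self, rng):
        G = rng.normal(size=(4, 2))
        C = np.array([[0.0], [1.0], [1.0], [0.0]])
        C_hat = augment_confounds(C)
        model = fit_adjustment(G, C_hat)
        for j in range(2):  # independent per-column least squares
            beta_j, *_ = np.linalg.lstsq(C_hat, G[:, j], rcond=None)
            np.testing.assert_allclose(model.beta[:, j], beta_j, atol=1e-10)
        resid = apply_adjustment(G, C_hat, model)
        oracle = G - C_hat @ np.linalg.lstsq(C_hat, G, rcond=None)[0]
        np.testing.assert_allclose(resid, oracle, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        G = rng.normal(size=(30, 8))
        C = rng.normal(size=(30, 2))
        adjusted, _ = adjust_features(G, C)
        C_hat = augment_confounds(C)
        cross = C_hat.T @ adjusted
        scale = np.abs(C_hat).max() * np.abs(G).max() * 30
        assert np.abs(cross).max() / scale < 1e-8

    def test_orthogonal_centered_features_have_zero_slopes(self, rng):
        C = np.array([[0.0], [1.0], [1.0], [0.0]])
        C_hat = augment_confounds(C)
        raw = rng.normal(size=(4, 3))
        G = raw - C_hat @ np.linalg.lstsq(C_hat, raw, rcond=None)[0]
        model = fit_adjustment(G, C_hat)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-10)

    def test_features_in_confound_span_adjust_to_zero(self, rng):
        C = rng.normal(size=(10, 2))
        C_hat = augment_confounds(C)
        G = C_hat @ rng.normal(size=(3, 4))
        adjusted, _ = adjust_features(G, C)
        np.testing.assert_allclose(adjusted, 0.0, atol=1e-9)

    def test_subset_all_rows_equals_full_fit(self, rng):
        G = rng.normal(size=(12, 5))
        C = rng.normal(size=(12, 1))
        a_full, _ = adjust_features(G, C)
        a_sub, _ = adjust_features(G, C, subset=np.arange(12))
        np.testing.assert_allclose(a_full, a_sub, atol=1e-12)

    def test_subset_fit_orthogonal_only_on_subset(self, rng):
        G = rng.normal(size=(20, 3))
        C = rng.normal(size=(20, 1))
        subset = np.arange(10)
        adjusted, _ = adjust_features(G, C, subset=subset)
        C_hat = augment_confounds(C)
        on_subset = np.abs(C_hat[subset].T @ adjusted[subset]).max()
        off_subset = np.abs(C_hat[10:].T @ adjusted[10:]).max()
        assert on_subset < 1e-8 * 20 * np.abs(G).max()
        assert off_subset > 1e-4  # no reason to vanish off the fitting subset

    def test_projector_idempotent(self, rng):
        G = rng.normal(size=(15, 6))
        C = rng.normal(size=(15, 2))
        once, _ = adjust_features(G, C)
        twice, _ = adjust_features(once, C)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rank_deficient_confounds_rejected(self, rng):
        C = rng.normal(size=(8, 1))
        C2 = np.hstack([C, 2 * C])  # second column linearly dependent
        with pytest.raises(SingularMatrixError):
            fit_adjustment(rng.normal(size=(8, 3)), augment_confounds(C2))


class TestDensityEstimation:
    def test_marginal_recovers_standard_normal(self):
        y = np.random.default_rng(0).normal(size=500)
        dens, _ = estimate_target_density(y)
        rel_err = np.abs(dens / st.norm.pdf(y) - 1.0)
        assert np.mean(rel_err < 0.15) >= 0.95

    def test_identical_targets_get_identical_density(self, rng):
        y = rng.normal(size=20)
        y[3] = y[11]
        dens, _ = estimate_target_density(y)
        assert dens[3] == pytest.approx(dens[11], abs=1e-14)

    def test_density_integrates_to_one(self, rng):
        y = rng.normal(2.0, 1.5, size=100)
        _, fit = estimate_target_density(y)
        pred = predict_gp(fit, np.zeros((1, 1)))
        grid = np.linspace(y.min() - 5 * y.std(), y.max() + 5 * y.std(), 4001)
        dens = st.norm.pdf(grid, pred.mean[0], np.sqrt(pred.variance[0]))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_conditional_approaches_marginal_under_independence(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=400)
        c = (rng.random(400) < 0.5).astype(float)[:, None]
        marg, _ = estimate_target_density(y)
        cond, _ = estimate_conditional_density(y, c)
        ratio = marg / cond
        assert np.mean((ratio > 0.8) & (ratio < 1.25)) >= 0.90

    def test_conditional_exceeds_marginal_near_group_means(self):
        rng = np.random.default_rng(4)
        c = (rng.random(300) < 0.5).astype(float)
        y = 2.0 * c + rng.normal(0, 0.1, size=300)
        marg, _ = estimate_target_density(y)
        cond, _ = estimate_conditional_density(y, c[:, None])
        near = np.abs(y - 2.0 * c) < 0.1
        assert np.all(cond[near] > marg[near])

    def test_identical_subject_pairs_deterministic(self, rng):
        y = rng.normal(size=30)
        c = (rng.random(30) < 0.5).astype(float)
        y[5], c[5] = y[20], c[20]
        cond, _ = estimate_conditional_density(y, c[:, None])
        assert cond[5] == pytest.approx(cond[20], abs=1e-14)


class TestInstanceWeights:
    def test_near_unity_under_independence(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=400)
        c = (rng.random(400) < 0.5).astype(float)[:, None]
        iw = compute_instance_weights(y, c, normalize=False)
        assert np.mean((iw.w > 0.8) & (iw.w < 1.25)) >= 0.95

    def test_rank_order_matches_normal_pdf_ratio_oracle(self):
        rng = np.random.default_rng(6)
        c = (rng.random(300) < 0.5).astype(float)
        y = 2.0 * c + rng.normal(0, 0.5, size=300)
        iw = compute_instance_weights(y, c[:, None], normalize=False)
        # oracle with exact normal pdfs: fitted-model-class marginal vs true conditional
        marg = st.norm.pdf(y, y.mean(), y.std(ddof=1))
        cond = st.norm.pdf(y, 2.0 * c, 0.5)
        rho = st.spearmanr(iw.w, marg / cond).statistic
        assert rho >= 0.9
        # atypical-for-their-group subjects carry the largest weights
        atypical = np.abs(y - 2.0 * c) > 1.0
        assert iw.w[atypical].mean() > iw.w[~atypical].mean()

    def test_weights_positive_and_ratio_consistent(self, rng):
        y = rng.normal(size=50)
        c = (rng.random(50) < 0.5).astype(float)[:, None]
        iw = compute_instance_weights(y, c, normalize=False)
        assert (iw.w > 0).all()
        np.testing.assert_allclose(iw.w, iw.p_marginal / iw.p_conditional, rtol=1e-12)
        normed = compute_instance_weights(y, c, normalize=True)
        assert normed.w.mean() == pytest.approx(1.0)
        np.testing.assert_allclose(normed.w / normed.w.sum(),
                                   normed.ratio / normed.ratio.sum(), rtol=1e-12)

    def test_determinism(self, rng):
        y = rng.normal(size=40)
        c = (rng.random(40) < 0.5).astype(float)[:, None]
        a = compute_instance_weights(y, c)
        b = compute_instance_weights(y, c)
        np.testing.assert_array_equal(a.w, b.w)


class TestStandardizedDifference:
    def test_hand_computed_fixture(self):
        rep = weighted_standardized_difference(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]),
            np.ones(4),
        )
        # means 1.5 / 3.5, variances 0.5 / 0.5 -> -2 / sqrt(0.5) = -2 sqrt(2)
        assert rep.std_diff_weighted == pytest.approx(-2.0 * np.sqrt(2.0))
        assert rep.std_diff_unweighted == pytest.approx(-2.0 * np.sqrt(2.0))

    def test_equal_weights_reduce_to_classical(self, rng):
        y = rng.normal(size=30)
        g = (rng.random(30) < 0.5).astype(int)
        g[0], g[1] = 0, 1
        rep = weighted_standardized_difference(y, g, np.full(30, 3.7))
        assert rep.std_diff_weighted == rep.std_diff_unweighted

    def test_zero_when_weighted_means_match(self):
        y = np.array([0.0, 2.0, 1.0, 1.0])
        rep = weighted_standardized_difference(y, [0, 0, 1, 1], np.ones(4))
        assert rep.std_diff_weighted == pytest.approx(0.0)

    def test_scale_equivariance(self, rng):
        y = rng.normal(size=25)
        g = (rng.random(25) < 0.5).astype(int)
        g[:2] = [0, 1]
        w = rng.uniform(0.5, 2.0, size=25)
        a = weighted_standardized_difference(y, g, w)
        b = weighted_standardized_difference(5.0 * y, g, w)
        assert a.std_diff_weighted == pytest.approx(b.std_diff_weighted, rel=1e-12)

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValidationError):
            weighted_standardized_difference(rng.normal(size=5), np.zeros(5), np.ones(5))


def test_balance_improvement_on_biased_samples():
    """Reweighting reduces |standardized difference| on confounded samples."""
    from deconfound.evaluate import draw_biased_sample
    from deconfound.simulate import PopulationSpec, generate_population

    rng = np.random.default_rng(11)
    improved = 0
    for s in range(10):
        pool = generate_population(PopulationSpec(n=300, d_features=3, seed=600 + s))
        samp = draw_biased_sample(pool.y, pool.C[:, 0], 100, 1.5, rng=rng)
        y, c = pool.y[samp.indices], pool.C[samp.indices, 0]
        iw = compute_instance_weights(y, c[:, None])
        rep = weighted_standardized_difference(y, c, iw.w)
        improved += rep.improved
    assert improved >= 9
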