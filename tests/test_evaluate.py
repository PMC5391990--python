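"""Splits, biased sampling, metrics, protocol bookkeeping, permutation test."""

import numpy as np
import pytest
from scipy import stats as st

from deconfound.data import Dataset
from deconfound.evaluate import (
    ProtocolConfig,
    balanced_mse,
    build_split_scheme,
    draw_biased_sample,
    half_split,
    mse,
    partition_by_target,
    restricted_permutation_test,
    run_protocol,
    signed_group_difference,
)
from deconfound.exceptions import MetricError, SamplingError, ValidationError
from deconfound.simulate import PopulationSpec, generate_population


class TestHalfSplit:
    def test_partition_properties(self):
        f1, f2 = half_split(8, np.random.default_rng(0))
        assert len(f1) == len(f2) == 4
        assert np.intersect1d(f1, f2).size == 0
        assert np.array_equal(np.sort(np.concatenate([f1, f2])), np.arange(8))

    def test_seed_determinism_and_variety(self):
        a1, _ = half_split(12, 7)
        a2, _ = half_split(12, 7)
        np.testing.assert_array_equal(a1, a2)
        distinct = {tuple(half_split(12, s)[0]) for s in range(20)}
        assert len(distinct) > 1


class TestBiasedSampling:
    @pytest.fixture
    def fold(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        c = (rng.random(200) < 0.5).astype(float)
        return y, c

    def test_indices_unique_and_in_fold(self, fold):
        y, c = fold
        fold_idx = np.arange(300, 500)
        samp = draw_biased_sample(y, c, 80, 1.5, rng=0, indices=fold_idx)
        assert len(np.unique(samp.indices)) == 80
        assert np.isin(samp.indices, fold_idx).all()
        assert samp.p_value < 0.05

    def test_unfiltered_null_pvalues_uniform(self):
        # each draw comes from a fresh null pool so the fold's own chance
        # association does not repeat across draws
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            y = rng.normal(size=200)
            c = (rng.random(200) < 0.5).astype(float)
            ps.append(draw_biased_sample(y, c, 80, 0.0, accept_p=None,
                                         rng=rng).p_value)
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_unbiased_acceptance_rule(self, fold):
        y, c = fold
        rng = np.random.default_rng(3)
        for _ in range(20):
            samp = draw_biased_sample(y, c, 80, 0.0, rng=rng)
            assert samp.p_value >= 0.05

    def test_biased_acceptance_is_fast(self, fold):
        y, c = fold
        hits = 0
        for s in range(20):
            samp = draw_biased_sample(y, c, 80, 1.5, rng=s, max_tries=50)
            hits += samp.n_tries <= 50 and samp.p_value < 0.05
        assert hits >= 19

    def test_failure_reports_best_p(self, fold):
        y, c = fold
        with pytest.raises(SamplingError, match="best achieved p"):
            # p < 1e-12 is essentially unreachable
            draw_biased_sample(y, c, 80, 1.5, accept_p=1e-12, rng=0, max_tries=5)

    def test_ratio_constraint(self, fold):
        y, c = fold
        samp = draw_biased_sample(y, c, 60, 1.0, rng=4, ratio=2.0)
        picked_c = c[samp.indices]
        assert np.sum(picked_c == 0) == 40 and np.sum(picked_c == 1) == 20


class TestMetrics:
    def test_mse_examples(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0
        assert mse([1, 2, 3], [1.5, 2.5, 3.5]) == pytest.approx(0.25)
        assert mse([1, 2, 3], [2, 2, 2]) == pytest.approx(2.0 / 3.0)
        with pytest.raises(ValidationError):
            mse([1, 2], [1])

    def test_partition_median_and_tie_rule(self):
        part = partition_by_target(np.arange(1, 11))
        assert part.threshold == 5.5
        low, high = part.masks(np.arange(1, 11))
        assert low.sum() == 5
        # ties at the threshold fall in the low subset (y <= threshold)
        part2 = partition_by_target(np.array([27, 28, 28, 29, 30, 30.0]))
        low2, _ = part2.masks(np.array([28.0, 29.0]))
        np.testing.assert_array_equal(low2, [True, False])

    def test_degenerate_targets_rejected(self):
        with pytest.raises(MetricError):
            partition_by_target(np.full(6, 3.0))

    def test_empty_subset_rejected(self):
        part = partition_by_target(np.arange(10.0))
        with pytest.raises(MetricError):
            balanced_mse(np.full(4, 20.0), np.zeros(4), [0, 1, 0, 1], part)

    def test_balanced_mse_hand_fixture(self):
        # 8 subjects, low subset: errors 2,0 (group 0), 0,0 (group 1)
        y = np.array([1.0, 1, 1, 1, 9, 9, 9, 9])
        yhat = y + np.array([np.sqrt(2), 0, 0, 0, 2, 0, 0, 0])
        g = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        part = partition_by_target(y)
        per_subset, overall = balanced_mse(y, yhat, g, part)
        assert per_subset[0] == pytest.approx(0.5 * (1.0 + 0.0))
        assert per_subset[1] == pytest.approx(0.5 * (2.0 + 0.0))
        assert overall == pytest.approx(0.5 * 0.5 + 0.5 * 1.0)

    def test_balanced_equals_plain_when_groups_match(self, rng):
        y = rng.normal(size=40)
        err = rng.normal(size=20)
        yhat = y + np.concatenate([err, err])  # identical errors per group
        g = np.array([0] * 20 + [1] * 20)
        part = partition_by_target(y)
        # per-subset balanced values average two equal group MSEs
        per_subset, _ = balanced_mse(y, yhat, g, part)
        assert np.isfinite(per_subset).all()

    def test_balanced_value_ignores_group_sizes(self):
        # low subset: group 0 has one subject with error 4, group 1 has three
        # with error 0 -> balanced value is 2 regardless of the 1:3 imbalance
        y = np.array([0.0, 0, 0, 0, 9, 9])
        yhat = np.array([2.0, 0, 0, 0, 9, 9])
        g = np.array([0, 1, 1, 1, 0, 1])
        per_subset, _ = balanced_mse(y, yhat, g, partition_by_target(y))
        assert per_subset[0] == pytest.approx(2.0)

    def test_signed_difference_antisymmetry(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(size=30)
        g = (rng.random(30) < 0.5).astype(int)
        g[:4] = [0, 1, 0, 1]
        part = partition_by_target(y)
        s1, sum1 = signed_group_difference(y, yhat, g, part)
        s2, sum2 = signed_group_difference(y, yhat, 1 - g, part)
        np.testing.assert_allclose(s1, -s2, atol=1e-12)
        assert sum1 == pytest.approx(sum2)

    def test_signed_difference_zero_for_matched_errors(self):
        y = np.array([0.0, 0, 10, 10, 0, 0, 10, 10])
        yhat = y + np.array([1.0, 1, 2, 2, 1, 1, 2, 2])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        signed, summary = signed_group_difference(y, yhat, g, partition_by_target(y))
        np.testing.assert_allclose(signed, 0.0, atol=1e-12)
        assert summary == 0.0


@pytest.fixture(scope="module")
def small_pool():
    return generate_population(PopulationSpec(n=80, d_features=10, seed=5))


class TestProtocol:
    def test_bit_exact_reproducibility(self, small_pool):
        cfg = ProtocolConfig(sample_size=20, J=1)
        a = run_protocol(small_pool, ["images_only"], cfg, seed=1)
        b = run_protocol(small_pool, ["images_only"], cfg, seed=1)
        assert a.reports["images_only"].per_run.equals(
            b.reports["images_only"].per_run)

    def test_duplicate_strategy_gives_identical_reports(self, small_pool):
        cfg = ProtocolConfig(sample_size=20, J=1)
        scheme = build_split_scheme(small_pool, cfg, 2)
        r1 = run_protocol(small_pool, ["images_only"], cfg, scheme=scheme)
        r2 = run_protocol(small_pool, ["images_only"], cfg, scheme=scheme)
        assert r1.reports["images_only"].mse == r2.reports["images_only"].mse

    def test_averages_match_per_run_bookkeeping(self, small_pool):
        cfg = ProtocolConfig(sample_size=20, J=2)
        res = run_protocol(small_pool, ["images_only"], cfg, seed=3)
        rep = res.reports["images_only"]
        assert len(rep.per_run) == 4  # 2 folds x J
        assert rep.mse == pytest.approx(rep.per_run["mse"].mean())
        assert rep.balanced_mse == pytest.approx(rep.per_run["balanced_mse"].mean())

    def test_population_check(self, small_pool):
        from deconfound.simulate import generate_conditional_null
        biased_pool = generate_conditional_null(n=80, d_features=5,
                                                target_shift=2.0, seed=0)
        cfg = ProtocolConfig(sample_size=20, J=1, check_population=True,
                             accept_p=None)
        with pytest.raises(ValidationError):
            run_protocol(biased_pool, ["images_only"], cfg, seed=0)

    def test_metrics_frame_layout(self, small_pool):
        cfg = ProtocolConfig(sample_size=20, J=1)
        res = run_protocol(small_pool, ["images_only", "adjusted_images"], cfg, seed=4)
        frame = res.metrics_frame()
        assert set(frame["strategy"]) == {"images_only", "adjusted_images"}
        assert {"mse", "balanced_mse", "group_difference_mse"} <= set(frame.columns)


class TestRestrictedPermutation:
    def test_within_level_multisets_preserved(self, small_pool):
        from deconfound.evaluate import _permute_within_levels
        rng = np.random.default_rng(0)
        folds = half_split(small_pool.n, rng)
        permuted = _permute_within_levels(small_pool, folds, rng)
        for fold in folds:
            for lev in (0.0, 1.0):
                rows = fold[small_pool.C[fold, 0] == lev]
                assert sorted(permuted.y[rows]) == sorted(small_pool.y[rows])
        assert not np.array_equal(permuted.y, small_pool.y)

    def test_p_value_bounds(self, small_pool):
        cfg = ProtocolConfig(sample_size=20, J=1,
                             fit_options={"optimize_hyperparameters": False})
        res = restricted_permutation_test(small_pool, "images_only", cfg,
                                          n_perm=20, seed=6, metrics=("mse",))
        p = res.p_values["mse"]
        assert 1.0 / 20 <= p <= 1.0
        assert len(res.permuted) == 19

    def test_signal_detected_against_null(self, small_pool):
        # strong feature signal: observed MSE should beat nearly all permutations
        cfg = ProtocolConfig(sample_size=25, J=1,
                             fit_options={"optimize_hyperparameters": False})
        res = restricted_permutation_test(small_pool, "images_only", cfg,
                                          n_perm=50, seed=7, metrics=("mse",))
        assert res.p_values["mse"] <= 2.0 / 50
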