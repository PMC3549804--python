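"""Likelihood core: p_k, pool/locus likelihoods, the naive estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from poolem import (LocusData, ModelParams, PoolCounts,
                    dataset_log_likelihood, minor_read_prob,
                    naive_frequency, pool_log_likelihood)


def brute_force_pool_loglik(n_minor, n_total, K, params):
    """Direct mixture sum with exact binomial pmfs (oracle)."""
    total = 0.0
    for k in range(K + 1):
        p_k = (k / K) * (1 - params.beta) + ((K - k) / K) * params.alpha
        total += binom.pmf(n_minor, n_total, p_k) * binom.pmf(k, K, params.f)
    return np.log(total)


class TestMinorReadProb:
    @pytest.mark.parametrize("k,expected", [(0, 0.01), (100, 0.99), (50, 0.5)])
    def test_boundary_and_symmetry(self, k, expected):
        params = ModelParams(f=0.1, alpha=0.01, beta=0.01)
        assert minor_read_prob(k, 100, params) == pytest.approx(expected)

    def test_out_of_range_carrier_count_rejected(self):
        params = ModelParams(f=0.1, alpha=0.01, beta=0.01)
        with pytest.raises(ValueError):
            minor_read_prob(5, 4, params)
        with pytest.raises(ValueError):
            minor_read_prob(-1, 4, params)

    def test_monotone_in_k_when_alpha_below_one_minus_beta(self):
        params = ModelParams(f=0.1, alpha=0.02, beta=0.05)
        p = minor_read_prob(np.arange(11), 10, params)
        assert np.all(np.diff(p) >= 0)
        assert p.min() >= min(params.alpha, 1 - params.beta) - 1e-15
        assert p.max() <= max(params.alpha, 1 - params.beta) + 1e-15


class TestPoolLogLikelihood:
    def test_f_zero_collapses_to_error_binomial(self):
        params = ModelParams(f=0.0, alpha=0.01, beta=0.3)
        pool = PoolCounts(95, 5)
        expected = binom.logpmf(5, 100, 0.01)
        assert pool_log_likelihood(pool, 10, params) == pytest.approx(expected)

    def test_f_one_collapses_to_k_equals_K_term(self):
        params = ModelParams(f=1.0, alpha=0.01, beta=0.01)
        pool = PoolCounts(5, 95)
        expected = binom.logpmf(95, 100, 0.99)
        assert pool_log_likelihood(pool, 10, params) == pytest.approx(expected)

    def test_matches_brute_force_mixture(self, toy_locus):
        params = ModelParams(f=0.3, alpha=0.01, beta=0.02)
        for pool in toy_locus.pools:
            expected = brute_force_pool_loglik(pool.n_minor, pool.n_total,
                                               toy_locus.K, params)
            got = pool_log_likelihood(pool, toy_locus.K, params)
            assert got == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(K=st.integers(1, 6), n=st.integers(0, 20),
           f=st.floats(0.0, 1.0), a=st.floats(0.0, 0.5),
           b=st.floats(0.0, 0.5))
    def test_normalization_over_all_count_splits(self, K, n, f, a, b):
        """Probabilities over every (n0, n1) split of n reads sum to 1."""
        params = ModelParams(f=f, alpha=a, beta=b)
        total = sum(np.exp(pool_log_likelihood(PoolCounts(n - m, m), K, params))
                    for m in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(K=st.integers(1, 10), n=st.integers(1, 50), seed=st.integers(0, 10**6))
    def test_matches_direct_sum_for_moderate_sizes(self, K, n, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(0, n + 1))
        params = ModelParams(f=float(rng.uniform(0.01, 0.99)),
                             alpha=float(rng.uniform(0.001, 0.2)),
                             beta=float(rng.uniform(0.001, 0.2)))
        expected = brute_force_pool_loglik(n1, n, K, params)
        got = pool_log_likelihood(PoolCounts(n - n1, n1), K, params)
        assert got == pytest.approx(expected, abs=1e-10)


class TestDatasetLogLikelihood:
    def test_single_pool_equals_pool_likelihood(self):
        params = ModelParams(f=0.2, alpha=0.01, beta=0.01)
        pool = PoolCounts(8, 2)
        locus = LocusData((pool,), 4)
        assert dataset_log_likelihood(locus, params) == pytest.approx(
            pool_log_likelihood(pool, 4, params))

    def test_duplicated_pool_doubles_log_likelihood(self):
        params = ModelParams(f=0.2, alpha=0.01, beta=0.01)
        pool = PoolCounts(8, 2)
        single = LocusData((pool,), 4)
        double = LocusData((pool, pool), 4)
        assert dataset_log_likelihood(double, params) == pytest.approx(
            2 * dataset_log_likelihood(single, params))

    def test_mixed_pools_sum_term_by_term(self, toy_locus):
        params = ModelParams(f=0.15, alpha=0.03, beta=0.01)
        expected = sum(brute_force_pool_loglik(p.n_minor, p.n_total,
                                               toy_locus.K, params)
                       for p in toy_locus.pools)
        assert dataset_log_likelihood(toy_locus, params) == pytest.approx(
            expected, abs=1e-10)


class TestNaiveFrequency:
    def test_arithmetic(self, rare_locus):
        assert naive_frequency(rare_locus) == pytest.approx(15 / 2000)

    def test_zero_minor_reads(self):
        locus = LocusData((PoolCounts(10, 0), PoolCounts(20, 0)), 4)
        assert naive_frequency(locus) == 0.0

    def test_no_reads_raises(self):
        locus = LocusData((PoolCounts(0, 0),), 4)
        with pytest.raises(ValueError):
            naive_frequency(locus)

    def test_expectation_matches_error_inflation(self, rng):
        """Mean of f_avg over replicates approaches f(1-b) + (1-f)a."""
        from poolem import SimDesign, simulate_replicates
        design = SimDesign(f=0.01, alpha_start=0.01, n=1000, K=100, G=10,
                           replicates=2000, error_rate_spread=0.0)
        batch = simulate_replicates(design, rng)
        expected = 0.01 * 0.99 + 0.99 * 0.01
        assert batch.naive.mean() == pytest.approx(expected, rel=0.05)


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PoolCounts(-1, 5)

    def test_parameter_ranges_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(f=1.5, alpha=0.1, beta=0.1)
        with pytest.raises(ValueError):
            ModelParams(f=0.5, alpha=1.0, beta=0.1)

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError):
            LocusData((), 4)
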