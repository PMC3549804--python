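"""EM estimator: E-step oracles, M-step arithmetic, fit properties."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from poolem import (EMConfig, LocusData, ModelParams, PoolCounts,
                    SimDesign, dataset_log_likelihood,
                    e_step_expected_carriers, e_step_expected_match_counts,
                    fit_case_control, fit_em, fit_restricted, m_step_update,
                    naive_frequency, simulate_replicates)
from poolem.em import SufficientStats
from conftest import random_locus


def posterior_carrier_oracle(pool, K, params):
    """Direct normalized posterior mean over the K+1 carrier states."""
    k = np.arange(K + 1)
    p_k = (k / K) * (1 - params.beta) + ((K - k) / K) * params.alpha
    w = binom.pmf(k, K, params.f) * binom.pmf(pool.n_minor, pool.n_total, p_k)
    return float((k * w).sum() / w.sum())


def latent_enumeration_oracle(pool, K, params):
    """Full enumeration over (C, true states I, observed states r).

    Fixes one ordered observation vector consistent with the counts (the
    reads are exchangeable) and computes E(T11, T10, T01, T00) by summing
    over every latent configuration.  Exponential in n; keep n tiny.
    """
    n1, n = pool.n_minor, pool.n_total
    r_vec = [1] * n1 + [0] * (n - n1)
    f, a, b = params.f, params.alpha, params.beta
    joint = 0.0
    exp_t = np.zeros(4)  # T11, T10, T01, T00
    for c in range(K + 1):
        pc = binom.pmf(c, K, f)
        for i_vec in itertools.product([0, 1], repeat=n):
            p = pc
            for i in i_vec:
                p *= (c / K) if i else (1 - c / K)
            for i, r in zip(i_vec, r_vec):
                p *= {(1, 1): 1 - b, (1, 0): b, (0, 1): a, (0, 0): 1 - a}[(i, r)]
            joint += p
            t = np.array([sum(i * r for i, r in zip(i_vec, r_vec)),
                          sum(i * (1 - r) for i, r in zip(i_vec, r_vec)),
                          sum((1 - i) * r for i, r in zip(i_vec, r_vec)),
                          sum((1 - i) * (1 - r) for i, r in zip(i_vec, r_vec))])
            exp_t = exp_t + p * t
    return exp_t / joint


class TestEStepCarriers:
    def test_f_zero_pins_posterior_at_zero(self):
        params = ModelParams(f=0.0, alpha=0.01, beta=0.01)
        assert e_step_expected_carriers(PoolCounts(8, 2), 4, params) == 0.0

    def test_no_reads_returns_prior_mean(self):
        params = ModelParams(f=0.3, alpha=0.01, beta=0.01)
        got = e_step_expected_carriers(PoolCounts(0, 0), 10, params)
        assert got == pytest.approx(10 * 0.3)

    def test_matches_direct_posterior(self, toy_locus):
        params = ModelParams(f=0.3, alpha=0.01, beta=0.02)
        for pool in toy_locus.pools:
            assert e_step_expected_carriers(pool, toy_locus.K, params) == \
                pytest.approx(posterior_carrier_oracle(pool, toy_locus.K, params),
                              abs=1e-12)


class TestEStepMatchCounts:
    def test_f_zero_attributes_everything_to_error(self):
        params = ModelParams(f=0.0, alpha=0.01, beta=0.01)
        t11, t10, t01, t00 = e_step_expected_match_counts(
            PoolCounts(8, 2), 4, params)
        assert (t11, t10) == (0.0, 0.0)
        assert t01 == pytest.approx(2.0)
        assert t00 == pytest.approx(8.0)

    def test_no_errors_means_observed_equals_truth(self):
        params = ModelParams(f=0.3, alpha=0.0, beta=0.0)
        t11, t10, t01, t00 = e_step_expected_match_counts(
            PoolCounts(8, 2), 4, params)
        assert t11 == pytest.approx(2.0)
        assert t00 == pytest.approx(8.0)
        assert t10 == pytest.approx(0.0)
        assert t01 == pytest.approx(0.0)

    @pytest.mark.parametrize("n_major,n_minor", [(1, 2), (3, 0), (2, 2)])
    def test_matches_full_latent_enumeration(self, n_major, n_minor):
        params = ModelParams(f=0.35, alpha=0.08, beta=0.12)
        pool = PoolCounts(n_major, n_minor)
        got = e_step_expected_match_counts(pool, 2, params)
        expected = latent_enumeration_oracle(pool, 2, params)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_partition_identities(self, toy_locus):
        """T11+T01 = n1, T10+T00 = n0 for any parameters."""
        params = ModelParams(f=0.2, alpha=0.05, beta=0.07)
        for pool in toy_locus.pools:
            t11, t10, t01, t00 = e_step_expected_match_counts(
                pool, toy_locus.K, params)
            assert t11 + t01 == pytest.approx(pool.n_minor, abs=1e-9)
            assert t10 + t00 == pytest.approx(pool.n_major, abs=1e-9)


class TestMStep:
    def test_arithmetic(self):
        stats = SufficientStats(expected_carriers=6.0, t11=50, t10=5,
                                t01=1, t00=99)
        prev = ModelParams(f=0.1, alpha=0.05, beta=0.05)
        config = EMConfig(estimate_beta="free")
        params = m_step_update(stats, n_pools=3, K=10, previous=prev,
                               config=config)
        assert params.f == pytest.approx(6.0 / 30)
        assert params.alpha == pytest.approx(1 / 100)
        assert params.beta == pytest.approx(5 / 55)

    def test_zero_denominator_freezes_parameter(self):
        stats = SufficientStats(expected_carriers=0.0, t11=0, t10=0,
                                t01=2, t00=98)
        prev = ModelParams(f=0.1, alpha=0.05, beta=0.33)
        params = m_step_update(stats, 1, 10, previous=prev,
                               config=EMConfig(estimate_beta="free"))
        assert params.beta == pytest.approx(0.33)
        assert params.alpha == pytest.approx(0.02)

    def test_full_iteration_matches_hand_computation(self):
        """E-step on a 2-pool toy then M-step, against scalar hand math."""
        locus = LocusData((PoolCounts(8, 2), PoolCounts(9, 1)), 2)
        params = ModelParams(f=0.2, alpha=0.05, beta=0.05)
        ec = sum(e_step_expected_carriers(p, 2, params) for p in locus.pools)
        ts = np.sum([e_step_expected_match_counts(p, 2, params)
                     for p in locus.pools], axis=0)
        stats = SufficientStats(ec, *ts)
        updated = m_step_update(stats, 2, 2, previous=params,
                                config=EMConfig(estimate_beta="free"))
        assert updated.f == pytest.approx(ec / 4)
        assert updated.alpha == pytest.approx(ts[2] / (ts[2] + ts[3]))
        assert updated.beta == pytest.approx(ts[1] / (ts[1] + ts[0]))


class TestFitEM:
    def test_monotone_log_likelihood(self, rng):
        config = EMConfig(track_history=True, estimate_beta="free")
        for _ in range(20):
            locus = random_locus(rng)
            fit = fit_em(locus, config)
            assert np.all(np.diff(fit.history) >= -1e-9)

    def test_all_major_reads_drives_f_to_boundary(self):
        locus = LocusData((PoolCounts(50, 0), PoolCounts(60, 0)), 4)
        fit = fit_em(locus)
        assert fit.params.f < 1e-4

    def test_expected_carriers_within_range(self, rare_locus):
        fit = fit_em(rare_locus)
        assert np.all(fit.expected_carriers >= 0)
        assert np.all(fit.expected_carriers <= rare_locus.K)

    def test_matches_grid_search_on_tiny_instances(self, rng):
        """EM's optimum is no worse than a dense (f, alpha, beta) grid."""
        config = EMConfig(estimate_beta="free", tolerance=1e-12,
                          max_iterations=3000, f_upper_bound=1.0)
        fs = np.linspace(0, 1.0, 81)
        rates = np.linspace(0, 0.4, 41)
        for _ in range(5):
            locus = random_locus(rng, K_max=3, G_max=2, n_max=6)
            fit = fit_em(locus, config)
            best = -np.inf
            for f in fs:
                for a in rates:
                    ll = dataset_log_likelihood(
                        locus, ModelParams(f=f, alpha=a, beta=a))
                    best = max(best, ll)
            # grid ties beta=alpha; EM with free beta must do at least as well
            assert fit.log_likelihood >= best - 5e-3

    def test_unbiased_at_standard_design(self, rng):
        """Mean of f_em over replicates is statistically centered on f
        (the tied-beta estimator; free beta carries a small documented
        inflation from the beta ridge)."""
        from poolem._batch import em_single
        design = SimDesign(f=0.01, alpha_start=0.005, n=3000, K=100, G=10,
                           replicates=400)
        batch = simulate_replicates(design, rng)
        fit = em_single(batch.n_minor.astype(float),
                        batch.n_total.astype(float), 100,
                        EMConfig(estimate_beta="tied"))
        se = fit.f.std(ddof=1) / np.sqrt(len(fit.f))
        assert abs(fit.f.mean() - 0.01) < 4 * se

    def test_scalar_and_batch_agree(self, rng):
        """The vectorized kernel must match per-locus scalar E-steps."""
        from poolem._batch import em_single
        locus = random_locus(rng, K_max=4, G_max=3, n_max=20)
        config = EMConfig(estimate_beta="free")
        fit = fit_em(locus, config)
        params = fit.params
        ec = [e_step_expected_carriers(p, locus.K, params)
              for p in locus.pools]
        np.testing.assert_allclose(fit.expected_carriers, ec, atol=1e-8)


class TestFitRestricted:
    def test_f_zero_closed_form(self, rare_locus):
        fit = fit_restricted(rare_locus, "f=0")
        assert fit.params.f == 0.0
        assert fit.params.alpha == pytest.approx(15 / 2000)
        expected_ll = sum(binom.logpmf(m, 1000, 15 / 2000) for m in (10, 5))
        assert fit.log_likelihood == pytest.approx(expected_ll)
        assert np.isnan(fit.params.beta)

    def test_restricted_never_beats_unrestricted(self, rng):
        for _ in range(30):
            locus = random_locus(rng, K_max=4, G_max=3, n_max=30)
            if locus.n_total.sum() == 0:
                continue
            full = fit_em(locus)
            null = fit_restricted(locus, "f=0")
            assert null.log_likelihood <= full.log_likelihood + 1e-6

    def test_shared_f_on_identical_groups_matches_single_fit(self, rare_locus):
        shared = fit_restricted((rare_locus, rare_locus), "shared-f")
        single = fit_em(rare_locus)
        assert shared.f_case == pytest.approx(shared.f_control)
        assert shared.f_case == pytest.approx(single.params.f, abs=1e-4)

    def test_fixed_f_holds_frequency(self, rare_locus):
        fit = fit_restricted(rare_locus, "fixed-f", f_value=0.003)
        assert fit.params.f == pytest.approx(0.003)


class TestVarianceDecomposition:
    def test_em_tracks_carrier_fraction_closer_than_truth(self, rng):
        """Most of f_em's variance is cohort sampling: MSE vs f_frac is
        far below MSE vs f at rare frequencies."""
        from poolem._batch import em_single
        design = SimDesign(f=0.001, alpha_start=0.005, n=3000, K=100, G=10,
                           replicates=300)
        batch = simulate_replicates(design, rng)
        fit = em_single(batch.n_minor.astype(float),
                        batch.n_total.astype(float), 100, EMConfig())
        mse = np.mean((fit.f - 0.001) ** 2)
        cg = np.mean((fit.f - batch.f_frac) ** 2)
        assert cg < 0.5 * mse
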