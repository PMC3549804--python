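"""Maximum-likelihood estimation of (f, alpha, beta) by EM.

The latent variables are the per-pool carrier counts C_g and the true
allele state of each read.  Writing T11/T10/T01/T00 for the total numbers
of reads whose (true, observed) states are (minor, minor), (minor, major),
(major, minor) and (major, major), the M-step is

    f     <- E(C) / (G K)
    alpha <- E(T01) / (E(T01) + E(T00))
    beta  <- E(T10) / (E(T10) + E(T11))

with the expectations computed in the E-step under the current parameters.
Beta is estimated freely by default, but it is poorly identified when few
chromosomes carry the minor allele; a tied mode (beta = alpha, which
removes that ridge and its small upward bias on f) and a fixed-beta mode
are available.  The frequency is constrained to [0, f_upper_bound] (default
0.5) to break the (f, alpha, beta) <-> (1-f, beta, alpha) symmetry of the
likelihood.

Restricted fits needed by the test statistics are also provided: under
f = 0 the likelihood collapses to a single binomial with closed-form
alpha_hat = sum(n1_g) / sum(n_g) (beta unidentifiable); under a shared-f
restriction the EM runs over two groups with a common frequency and common
error rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from . import _batch
from .model import LocusData, ModelParams, PoolCounts, minor_read_prob

__all__ = [
    "EMConfig",
    "EMFit",
    "SufficientStats",
    "CaseControlFit",
    "e_step_expected_carriers",
    "e_step_expected_match_counts",
    "m_step_update",
    "fit_em",
    "fit_case_control",
    "fit_restricted",
]


@dataclass(frozen=True)
class EMConfig:
    """Convergence, initialization and constraint settings for the EM.

    ``estimate_beta``: "free" (default; matches the full M-step, though the
    beta estimate itself is unreliable at rare frequencies), "tied"
    (beta = alpha), or "fixed" (beta held at ``beta_value``).
    ``tolerance`` is the absolute log-likelihood increase below which
    iteration stops.
    """

    max_iterations: int = 500
    tolerance: float = 1e-8
    estimate_beta: str = "free"
    beta_value: float = 0.0
    f_upper_bound: float = 0.5
    track_history: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.estimate_beta not in ("tied", "free", "fixed"):
            raise ValueError("estimate_beta must be 'tied', 'free' or 'fixed'")
        if not 0 < self.f_upper_bound <= 1:
            raise ValueError("f_upper_bound must lie in (0, 1]")


@dataclass
class EMFit:
    """Converged estimates with log-likelihood and iteration diagnostics."""

    params: ModelParams
    log_likelihood: float
    iterations_used: int
    converged: bool
    expected_carriers: np.ndarray | None = None
    history: np.ndarray | None = None


@dataclass
class CaseControlFit:
    """Two-group fit with shared error rates (and optionally shared f)."""

    f_case: float
    f_control: float
    alpha: float
    beta: float
    log_likelihood: float
    iterations_used: int
    converged: bool


@dataclass
class SufficientStats:
    """Expected complete-data sufficient statistics, summed over pools."""

    expected_carriers: float    # E(C)
    t11: float
    t10: float
    t01: float
    t00: float


def e_step_expected_carriers(pool: PoolCounts, K: int,
                             params: ModelParams) -> float:
    """Posterior mean of the pool's carrier count C_g given its read counts.

    E(C_g | data) = sum_k k w_k with w_k ∝ Bin(k; K, f) Bin(n1_g; n_g, p_k).
    With no reads the posterior is the prior, so the mean is K f.
    """
    k = np.arange(K + 1)
    p_k = minor_read_prob(k, K, params)
    w = binom.pmf(k, K, params.f) * binom.pmf(pool.n_minor, pool.n_total, p_k)
    tot = w.sum()
    if tot <= 0:
        raise FloatingPointError("zero posterior mass; data impossible under params")
    return float((k * w).sum() / tot)


def e_step_expected_match_counts(pool: PoolCounts, K: int,
                                 params: ModelParams):
    """Per-pool expected (T11, T10, T01, T00) contributions.

    The per-read expectation E(I r | counts) is
    sum_k (k/K)(1-beta) Bin(n1-1; n-1, p_k) Bin(k; K, f) / P(n0, n1),
    independent of the read index, and analogously for the other three
    (true, observed) combinations.  The four values sum to n_g; moreover
    T11 + T01 = n1_g and T10 + T00 = n0_g.
    """
    n1, n0, n = pool.n_minor, pool.n_major, pool.n_total
    if n == 0:
        return 0.0, 0.0, 0.0, 0.0
    k = np.arange(K + 1)
    p_k = minor_read_prob(k, K, params)
    prior = binom.pmf(k, K, params.f)
    marginal = float((prior * binom.pmf(n1, n, p_k)).sum())
    if marginal <= 0:
        raise FloatingPointError("zero marginal probability; data impossible under params")
    # Bin(-1; ., .) is 0, which correctly zeroes T11/T01 when n1 == 0.
    drop_minor = binom.pmf(n1 - 1, n - 1, p_k)
    keep_minor = binom.pmf(n1, n - 1, p_k)
    a, b = params.alpha, params.beta
    t11 = n * float((prior * (k / K) * (1 - b) * drop_minor).sum()) / marginal
    t01 = n * float((prior * ((K - k) / K) * a * drop_minor).sum()) / marginal
    t10 = n * float((prior * (k / K) * b * keep_minor).sum()) / marginal
    t00 = n * float((prior * ((K - k) / K) * (1 - a) * keep_minor).sum()) / marginal
    return t11, t10, t01, t00


def m_step_update(stats: SufficientStats, n_pools: int, K: int,
                  previous: ModelParams,
                  config: EMConfig | None = None) -> ModelParams:
    """One M-step: closed-form updates from the expected sufficient stats.

    Zero denominators (no expected mass for a truth class) freeze the
    affected error rate at its previous value.
    """
    config = config or EMConfig()
    f = min(max(stats.expected_carriers / (n_pools * K), 0.0),
            config.f_upper_bound)
    if config.estimate_beta == "tied":
        den = stats.t01 + stats.t10 + stats.t00 + stats.t11
        a = (stats.t01 + stats.t10) / den if den > 0 else previous.alpha
        b = a
    else:
        den_a = stats.t01 + stats.t00
        a = stats.t01 / den_a if den_a > 0 else previous.alpha
        if config.estimate_beta == "free":
            den_b = stats.t10 + stats.t11
            b = stats.t10 / den_b if den_b > 0 else previous.beta
        else:
            b = config.beta_value
    return ModelParams(f=f, alpha=min(a, 1 - 1e-12), beta=min(b, 1 - 1e-12))


def _counts(locus: LocusData):
    return (locus.n_minor[None, :].astype(float),
            locus.n_total[None, :].astype(float))


def fit_em(locus: LocusData, config: EMConfig | None = None) -> EMFit:
    """Maximum-likelihood fit of (f, alpha, beta) for one locus by EM.

    Alternates E and M steps until the log-likelihood increase falls below
    ``config.tolerance`` or ``config.max_iterations`` is reached.  The
    log-likelihood is nondecreasing across iterations (EM guarantee);
    enable ``config.track_history`` to record the trajectory.
    """
    config = config or EMConfig()
    if int(locus.n_total.sum()) == 0:
        raise ValueError("fit_em requires at least one pool with reads")
    n1, nt = _counts(locus)
    fit, _, _ = _batch.em_single_safe(n1, nt, locus.K, config)
    beta = fit.beta[0]
    return EMFit(
        params=ModelParams(f=float(fit.f[0]), alpha=float(fit.alpha[0]),
                           beta=float(beta)),
        log_likelihood=float(fit.loglik[0]),
        iterations_used=int(fit.iterations[0]),
        converged=bool(fit.converged[0]),
        expected_carriers=fit.ec_pool[0].copy(),
        history=(np.array([h[0] for h in fit.history])
                 if config.track_history else None),
    )


def fit_case_control(case: LocusData, control: LocusData,
                     share_f: bool = False,
                     config: EMConfig | None = None) -> CaseControlFit:
    """Joint fit over case and control pools with shared error rates.

    With ``share_f`` the frequency is common to both groups (the
    restricted fit of the association test); otherwise each group gets
    its own frequency.  The two groups may have different pool sizes K.
    """
    config = config or EMConfig()
    n1a, nta = _counts(case)
    n1b, ntb = _counts(control)
    fit = _batch.em_two_group(n1a, nta, case.K, n1b, ntb, control.K,
                              config, share_f=share_f)
    return CaseControlFit(
        f_case=float(fit.f_a[0]), f_control=float(fit.f_b[0]),
        alpha=float(fit.alpha[0]), beta=float(fit.beta[0]),
        log_likelihood=float(fit.loglik[0]),
        iterations_used=int(fit.iterations[0]),
        converged=bool(fit.converged[0]),
    )


def fit_restricted(loci, restriction: str = "f=0", *,
                   f_value: float | None = None,
                   config: EMConfig | None = None):
    """Maximize the likelihood subject to a restriction on f.

    ``loci`` is a LocusData or a (case, control) pair.  Restrictions:

    - ``"f=0"``: closed form.  The mixture collapses to its k = 0 term,
      alpha_hat = sum(n1_g)/sum(n_g) over all supplied pools, and beta is
      unidentifiable (reported as NaN).  Returns an EMFit.
    - ``"shared-f"``: requires a (case, control) pair; EM with a common
      (f, alpha, beta).  Returns a CaseControlFit.
    - ``"fixed-f"``: single locus with f held at ``f_value``.  Returns an
      EMFit.

    The restricted log-likelihood never exceeds the unrestricted fit on
    the same data.
    """
    config = config or EMConfig()
    group = (loci,) if isinstance(loci, LocusData) else tuple(loci)

    if restriction == "f=0":
        n1 = np.concatenate([g.n_minor for g in group]).astype(float)[None, :]
        nt = np.concatenate([g.n_total for g in group]).astype(float)[None, :]
        alpha, ll = _batch.null_loglik(n1, nt)
        # all-minor data gives the boundary MLE alpha = 1; report it a hair
        # inside the open interval (the log-likelihood uses the exact value)
        a_hat = min(float(alpha[0]), 1.0 - 1e-12)
        return EMFit(
            params=ModelParams(f=0.0, alpha=a_hat, beta=math.nan),
            log_likelihood=float(ll[0]), iterations_used=0, converged=True,
            expected_carriers=np.zeros(nt.shape[1]),
        )
    if restriction == "shared-f":
        if len(group) != 2:
            raise ValueError("shared-f restriction needs a (case, control) pair")
        return fit_case_control(group[0], group[1], share_f=True, config=config)
    if restriction == "fixed-f":
        if f_value is None:
            raise ValueError("fixed-f restriction needs f_value")
        if len(group) != 1:
            raise ValueError("fixed-f restriction takes a single locus")
        locus = group[0]
        n1, nt = _counts(locus)
        fit = _batch.em_single(n1, nt, locus.K, config, fix_f=f_value)
        return EMFit(
            params=ModelParams(f=float(fit.f[0]), alpha=float(fit.alpha[0]),
                               beta=float(fit.beta[0])),
            log_likelihood=float(fit.loglik[0]),
            iterations_used=int(fit.iterations[0]),
            converged=bool(fit.converged[0]),
            expected_carriers=fit.ec_pool[0].copy(),
        )
    raise ValueError(f"unknown restriction {restriction!r}")
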