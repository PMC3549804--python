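"""Binomial-mixture model for untagged pooled sequencing.

A biallelic locus is sequenced in ``G`` pools, each containing ``K``
chromosomes (``K/2`` individuals).  Within a pool the latent number of
chromosomes carrying the minor allele is ``C_g ~ Binomial(K, f)`` where
``f`` is the population minor allele frequency.  Conditional on
``C_g = k`` every read covering the locus shows the minor allele with
probability

    p_k = (k / K) * (1 - beta) + ((K - k) / K) * alpha,

where ``alpha = P(read minor | chromosome major)`` and
``beta = P(read major | chromosome minor)`` are the two directional
sequencing-error rates.  The observed minor-read count ``n1_g`` out of
``n_g`` reads is then ``Binomial(n_g, p_k)``, so the marginal probability
of a pool's counts is a (K+1)-component binomial mixture:

    P_g(n0_g, n1_g | f, alpha, beta)
        = sum_{k=0}^{K} Bin(n1_g; n_g, p_k) * Bin(k; K, f).

Pools are independent, so the locus likelihood is the product over pools.
All arithmetic here is carried out in log space with log-sum-exp over the
mixture components; binomial coefficients go through log-gamma so that
depths in the thousands do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "PoolCounts",
    "LocusData",
    "ModelParams",
    "minor_read_prob",
    "pool_log_likelihood",
    "dataset_log_likelihood",
    "naive_frequency",
]

# Margin used to pull probability parameters off exact 0/1 when a log of
# zero would otherwise make the whole likelihood -inf.  Stored parameter
# values are never altered; the clamp lives inside evaluation only.
_CLAMP = 1e-12


@dataclass(frozen=True)
class PoolCounts:
    """Observed allele read counts for one pool at one locus.

    ``n_major`` (n0_g) reads carry the major allele, ``n_minor`` (n1_g)
    the minor allele; the pool depth is their sum.
    """

    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError(
                f"read counts must be nonnegative, got ({self.n_major}, {self.n_minor})"
            )

    @property
    def n_total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class ModelParams:
    """Model parameters (f, alpha, beta).

    ``f`` is the minor allele frequency; ``alpha`` and ``beta`` are the
    directional error rates P(read 1 | true 0) and P(read 0 | true 1).
    ``beta`` may be NaN to mark "not estimated" (e.g. under the f = 0
    restriction, where beta is unidentifiable).
    """

    f: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if not math.isnan(self.beta) and not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must lie in [0, 1) or be NaN, got {self.beta}")


@dataclass(frozen=True)
class LocusData:
    """Counts for all G pools at one locus, plus the pool size K.

    ``chromosomes_per_pool`` is the number of chromosomes K (twice the
    number of individuals) in each pool.  ``locus_id`` is an opaque label,
    e.g. ``(chrom, pos, ref, alt)``.
    """

    pools: tuple[PoolCounts, ...]
    chromosomes_per_pool: int
    locus_id: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        if len(self.pools) < 1:
            raise ValueError("a locus needs at least one pool")
        if self.chromosomes_per_pool < 1:
            raise ValueError("chromosomes_per_pool (K) must be >= 1")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def K(self) -> int:
        return self.chromosomes_per_pool

    @property
    def n_minor(self) -> np.ndarray:
        return np.array([p.n_minor for p in self.pools])

    @property
    def n_major(self) -> np.ndarray:
        return np.array([p.n_major for p in self.pools])

    @property
    def n_total(self) -> np.ndarray:
        return np.array([p.n_total for p in self.pools])


def minor_read_prob(k, K: int, params: ModelParams):
    """Probability p_k that a read carries the minor allele given ``k``
    of the ``K`` pool chromosomes are carriers.

    Vectorized over ``k``.  Raises if any k falls outside [0, K].
    """
    k = np.asarray(k)
    if np.any((k < 0) | (k > K)):
        raise ValueError(f"carrier count k must lie in [0, {K}]")
    p = (k / K) * (1.0 - params.beta) + ((K - k) / K) * params.alpha
    return p if p.ndim else float(p)


def _pool_log_likelihood(n_minor: int, n_total: int, K: int,
                         f: float, alpha: float, beta: float) -> float:
    k = np.arange(K + 1)
    p_k = (k / K) * (1.0 - beta) + ((K - k) / K) * alpha
    with np.errstate(divide="ignore"):
        log_terms = binom.logpmf(n_minor, n_total, p_k) + binom.logpmf(k, K, f)
    return float(logsumexp(log_terms))


def pool_log_likelihood(pool: PoolCounts, K: int, params: ModelParams) -> float:
    """Log of the (K+1)-component mixture probability of one pool's counts.

    If the parameters sit exactly on a boundary that zeroes every mixture
    component (e.g. f = 0 with alpha = 0 but minor reads observed), the
    evaluation is retried with the offending probabilities clamped a
    machine-epsilon margin off 0/1.
    """
    if math.isnan(params.beta):
        raise ValueError("pool_log_likelihood requires a concrete beta")
    ll = _pool_log_likelihood(pool.n_minor, pool.n_total, K,
                              params.f, params.alpha, params.beta)
    if not np.isfinite(ll):
        clamp = lambda x: min(max(x, _CLAMP), 1.0 - _CLAMP)
        ll = _pool_log_likelihood(pool.n_minor, pool.n_total, K,
                                  clamp(params.f), clamp(params.alpha),
                                  clamp(params.beta))
    return ll


def dataset_log_likelihood(locus: LocusData, params: ModelParams) -> float:
    """Sum of pool log-likelihoods over the G independent pools."""
    return sum(pool_log_likelihood(p, locus.K, params) for p in locus.pools)


def naive_frequency(locus: LocusData) -> float:
    """Fraction of observed minor-allele reads, pooled over all pools.

    This is the naive frequency estimate f_avg = sum(n1_g) / sum(n_g);
    it is biased upward by sequencing error (expectation
    f(1-beta) + (1-f)alpha under the model).
    """
    total = int(locus.n_total.sum())
    if total == 0:
        raise ValueError("naive_frequency undefined: no reads in any pool")
    return float(locus.n_minor.sum() / total)
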