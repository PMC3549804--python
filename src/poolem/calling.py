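"""EM-SNP: likelihood-ratio SNP calling with boundary-corrected nulls.

A candidate variant is a true polymorphism if its minor allele frequency
is nonzero.  Because f = 0 sits on the boundary of the parameter space,
the likelihood-ratio statistic is not asymptotically chi-square; instead

- testing f0 = f1 = 0 jointly over cases and controls:
      Lambda ~ 1/4 I0 + 1/2 chi2_1 + 1/4 chi2_2
- testing f = 0 in a single group:
      Lambda_i ~ 1/2 I0 + 1/2 chi2_1

where I0 is a point mass at zero.  When the number of pools is small the
asymptotics are unreliable and a parametric bootstrap of the null supplies
the rejection threshold instead.  Candidate variants are ranked by the
magnitude of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from . import _batch
from .em import CaseControlFit, EMConfig, EMFit, fit_restricted
from .model import LocusData, ModelParams

__all__ = [
    "NullMixture",
    "JOINT_NULL",
    "SINGLE_NULL",
    "CallResult",
    "mixture_null_pvalue",
    "mixture_threshold",
    "lrt_single",
    "lrt_joint",
    "bootstrap_threshold",
    "rank_variants",
]

# Pool count below which the asymptotic mixture null is considered
# unreliable and the bootstrap is preferred.
ASYMPTOTIC_MIN_POOLS = 20


@dataclass(frozen=True)
class NullMixture:
    """Weights on {point mass at 0, chi2_1, chi2_2}; must sum to 1."""

    point_mass: float
    chi2_1: float
    chi2_2: float

    def __post_init__(self) -> None:
        w = (self.point_mass, self.chi2_1, self.chi2_2)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must be nonnegative and sum to 1, got {w}")


JOINT_NULL = NullMixture(0.25, 0.5, 0.25)
SINGLE_NULL = NullMixture(0.5, 0.5, 0.0)


@dataclass
class CallResult:
    """One candidate variant's test outcome."""

    locus_id: object
    lrt_statistic: float
    p_value: float
    mode: str                       # "joint" | "cases-only" | "controls-only"
    null_fit: object
    alt_fit: object
    rank: int | None = None


def mixture_null_pvalue(statistic: float, mixture: NullMixture) -> float:
    """P-value under the boundary mixture: the point mass contributes only
    at 0 (p(0) = 1, the conservative convention)."""
    if statistic < -_batch.LRT_SLACK:
        raise ValueError(f"LRT statistic must be >= 0, got {statistic}")
    return float(_batch.mixture_sf(max(statistic, 0.0), mixture.point_mass,
                                   mixture.chi2_1, mixture.chi2_2))


def mixture_threshold(gamma: float, mixture: NullMixture) -> float:
    """Rejection threshold t such that P(Lambda > t) = gamma under the mixture."""
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    cont = mixture.chi2_1 + mixture.chi2_2
    if gamma >= cont:          # the point mass alone absorbs the rest
        return 0.0
    sf = lambda t: (mixture.chi2_1 * chi2.sf(t, 1)
                    + mixture.chi2_2 * chi2.sf(t, 2) - gamma)
    hi = 10.0
    while sf(hi) > 0:
        hi *= 2.0
    return float(brentq(sf, 0.0, hi, xtol=1e-12))


def lrt_single(locus: LocusData, config: EMConfig | None = None,
               mode: str = "controls-only") -> CallResult:
    """Test f = 0 against f > 0 in one group of pools.

    Lambda_i = 2 (l_{f != 0} - l_{f = 0}); the null fit is the closed-form
    single-binomial MLE, the alternative the unrestricted EM fit.
    """
    config = config or EMConfig()
    null = fit_restricted(locus, "f=0", config=config)
    n1 = locus.n_minor[None, :].astype(float)
    nt = locus.n_total[None, :].astype(float)
    lam_arr, pval_arr, fit = _batch.lrt_single_batch(n1, nt, locus.K, config)
    alt = EMFit(params=ModelParams(f=float(fit.f[0]), alpha=float(fit.alpha[0]),
                                   beta=float(fit.beta[0])),
                log_likelihood=float(fit.loglik[0]),
                iterations_used=int(fit.iterations[0]),
                converged=bool(fit.converged[0]))
    return CallResult(locus_id=locus.locus_id, lrt_statistic=float(lam_arr[0]),
                      p_value=float(pval_arr[0]),
                      mode=mode, null_fit=null, alt_fit=alt)


def lrt_joint(case_locus: LocusData, control_locus: LocusData,
              config: EMConfig | None = None) -> CallResult:
    """Test f0 = f1 = 0 against (f0, f1) != (0, 0) over cases and controls.

    The alternative fits per-group frequencies with shared error rates;
    the null pools all reads into the closed-form single-binomial MLE.
    """
    config = config or EMConfig()
    null = fit_restricted((case_locus, control_locus), "f=0", config=config)
    lam_arr, pval_arr, fit = _batch.lrt_joint_batch(
        case_locus.n_minor[None, :].astype(float),
        case_locus.n_total[None, :].astype(float), case_locus.K,
        control_locus.n_minor[None, :].astype(float),
        control_locus.n_total[None, :].astype(float), control_locus.K, config)
    alt = CaseControlFit(f_case=float(fit.f_a[0]), f_control=float(fit.f_b[0]),
                         alpha=float(fit.alpha[0]), beta=float(fit.beta[0]),
                         log_likelihood=float(fit.loglik[0]),
                         iterations_used=int(fit.iterations[0]),
                         converged=bool(fit.converged[0]))
    return CallResult(locus_id=case_locus.locus_id or control_locus.locus_id,
                      lrt_statistic=float(lam_arr[0]),
                      p_value=float(pval_arr[0]),
                      mode="joint", null_fit=null, alt_fit=alt)


def bootstrap_threshold(locus: LocusData, gamma: float, replicates: int,
                        seed, control_locus: LocusData | None = None,
                        config: EMConfig | None = None) -> float:
    """Parametric-bootstrap rejection threshold t_gamma for the LRT.

    Fits the f = 0 null to the observed counts, simulates ``replicates``
    datasets from it (pure-error reads at the fitted alpha, observed
    depths), recomputes the statistic on each, and returns the empirical
    upper-gamma quantile.  If ``control_locus`` is given the joint
    statistic is bootstrapped, otherwise the single-group one.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    config = config or EMConfig()
    rng = np.random.default_rng(seed)
    loci = (locus,) if control_locus is None else (locus, control_locus)
    null = fit_restricted(loci, "f=0", config=config)
    a = null.params.alpha

    nt_a = np.broadcast_to(locus.n_total.astype(float), (replicates, locus.n_pools))
    n1_a = rng.binomial(locus.n_total[None, :], a, size=nt_a.shape).astype(float)
    if control_locus is None:
        lam, _, _ = _batch.lrt_single_batch(n1_a, nt_a, locus.K, config)
    else:
        nt_b = np.broadcast_to(control_locus.n_total.astype(float),
                               (replicates, control_locus.n_pools))
        n1_b = rng.binomial(control_locus.n_total[None, :], a,
                            size=nt_b.shape).astype(float)
        lam, _, _ = _batch.lrt_joint_batch(n1_a, nt_a, locus.K,
                                           n1_b, nt_b, control_locus.K, config)
    return float(np.quantile(lam, 1.0 - gamma))


def rank_variants(results: Sequence[CallResult]) -> list[CallResult]:
    """Order calls by descending LRT statistic, ties keeping input
    (coordinate) order, and assign 1-based ranks."""
    order = sorted(range(len(results)),
                   key=lambda i: (-results[i].lrt_statistic, i))
    ranked = []
    for rank, i in enumerate(order, start=1):
        ranked.append(replace_rank(results[i], rank))
    return ranked


def replace_rank(result: CallResult, rank: int) -> CallResult:
    return replace(result, rank=rank)
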