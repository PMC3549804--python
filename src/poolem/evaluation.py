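"""Accuracy, calibration and power metrics for the pooled-sequencing EM.

Estimator accuracy is measured against two targets: the population
frequency f (MSE, relative error) and the realized carrier fraction
f_frac = C/(KG) of each replicate (the "Cg" criterion).  The latter
separates estimation error from the binomial sampling variance
f(1-f)/(KG) of the cohort itself; for rare variants nearly all of the
EM estimator's MSE against f is that sampling variance.

Power of the SNP-calling and association LRTs is estimated by simulating
case-control replicates and counting rejections at the type-I error
gamma, with the rejection threshold taken from the asymptotic boundary
mixture when the number of pools is large (G >= 20) and from a
parametric bootstrap of the null otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import _batch
from .calling import (ASYMPTOTIC_MIN_POOLS, JOINT_NULL, SINGLE_NULL,
                      NullMixture, mixture_threshold)
from .em import EMConfig
from .simulate import (G_GRID, K_GRID, N_GRID, SimDesign, cell_rng,
                       simulate_case_control_replicates, simulate_replicates)

__all__ = [
    "mse_to_truth",
    "mse_to_ffrac",
    "relative_error",
    "trimmed_metrics",
    "grid_accuracy",
    "average_re",
    "scenario_comparison",
    "PowerEstimate",
    "estimate_power",
    "titv_ratio",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_NUCLEOTIDES = set("ACGT")


def mse_to_truth(estimates, truth: float) -> float:
    """Mean squared error of the estimates against the population f."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    return float(np.mean((estimates - truth) ** 2))


def mse_to_ffrac(estimates, f_frac) -> float:
    """Mean squared error against the paired per-replicate carrier
    fraction f_frac (the Cg criterion)."""
    estimates = np.asarray(estimates, dtype=float)
    f_frac = np.asarray(f_frac, dtype=float)
    if estimates.shape != f_frac.shape:
        raise ValueError("estimates and f_frac must be paired (equal length)")
    return float(np.mean((estimates - f_frac) ** 2))


def relative_error(estimates, truth: float) -> float:
    """RE = 100 |mean(estimates) - f| / f, in percent."""
    if truth <= 0:
        raise ValueError("relative error undefined at truth = 0")
    return float(100.0 * abs(np.mean(estimates) - truth) / truth)


def trimmed_metrics(estimates, reference, kappa: float) -> float:
    """MSE after symmetrically trimming the top and bottom kappa% of the
    estimate distribution (floor(R*kappa/100) values per tail).

    ``reference`` is either a scalar (truth f) or a paired f_frac vector,
    which is permuted together with the estimates.
    """
    if not 0 <= kappa < 50:
        raise ValueError("kappa must lie in [0, 50)")
    estimates = np.asarray(estimates, dtype=float)
    cut = int(math.floor(estimates.size * kappa / 100.0))
    order = np.argsort(estimates, kind="stable")
    keep = order[cut: estimates.size - cut] if cut else order
    est = estimates[keep]
    if np.ndim(reference) == 0:
        return mse_to_truth(est, float(reference))
    return mse_to_ffrac(est, np.asarray(reference, dtype=float)[keep])


def grid_accuracy(f: float, alpha_start: float, *,
                  n_values: Sequence[int] = N_GRID,
                  K_values: Sequence[int] = K_GRID,
                  G_values: Sequence[int] = G_GRID,
                  replicates: int = 200,
                  seed=0,
                  include_em: bool = True,
                  kappa: float | None = None,
                  config: EMConfig | None = None) -> pd.DataFrame:
    """Accuracy report over the (n, K, G) grid at one (f, alpha) pair.

    One row per cell with MSE/Cg/RE for the naive estimator and (if
    ``include_em``) the EM estimator; optional kappa-trimmed variants.
    """
    config = config or EMConfig()
    rows = []
    cells = list(product(n_values, K_values, G_values))
    for i, (n, K, G) in enumerate(cells):
        design = SimDesign(f=f, alpha_start=alpha_start, n=n, K=K, G=G,
                           replicates=replicates)
        batch = simulate_replicates(design, cell_rng(seed, i))
        naive = batch.naive
        ffrac = batch.f_frac
        row = {
            "f": f, "alpha_start": alpha_start, "n": n, "K": K, "G": G,
            "replicates": replicates,
            "mse_avg": mse_to_truth(naive, f),
            "cg_avg": mse_to_ffrac(naive, ffrac),
            "re_avg": relative_error(naive, f),
        }
        if include_em:
            fit = _batch.em_single(batch.n_minor, batch.n_total, K, config)
            row.update(
                mse_em=mse_to_truth(fit.f, f),
                cg_em=mse_to_ffrac(fit.f, ffrac),
                re_em=relative_error(fit.f, f),
            )
            if kappa is not None:
                row.update(
                    mse_em_trimmed=trimmed_metrics(fit.f, f, kappa),
                    cg_em_trimmed=trimmed_metrics(fit.f, ffrac, kappa),
                )
        if kappa is not None:
            row.update(
                mse_avg_trimmed=trimmed_metrics(naive, f, kappa),
                cg_avg_trimmed=trimmed_metrics(naive, ffrac, kappa),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def average_re(report: pd.DataFrame, estimator: str) -> float:
    """Unweighted mean of per-cell relative errors over the grid rows;
    ``estimator`` is "em" or "avg"."""
    col = f"re_{estimator}"
    if col not in report:
        raise KeyError(f"report has no column {col!r}")
    return float(report[col].mean())


def scenario_comparison(report: pd.DataFrame, metric: str = "mse") -> int:
    """Number of grid cells in which the EM estimator's error exceeds the
    naive estimator's; ``metric`` is "mse" or "cg"."""
    if metric not in ("mse", "cg"):
        raise ValueError("metric must be 'mse' or 'cg'")
    return int((report[f"{metric}_em"] > report[f"{metric}_avg"]).sum())


@dataclass
class PowerEstimate:
    power: float
    std_error: float
    threshold: float
    threshold_kind: str     # "asymptotic" | "bootstrap"
    replicates: int


def _bootstrap_threshold_for_design(design: SimDesign, mixture: NullMixture,
                                    gamma: float, arms: int,
                                    rng: np.random.Generator,
                                    config: EMConfig,
                                    boot_replicates: int = 1000) -> float:
    """Parametric-bootstrap threshold under the design's f = 0 null."""
    G, n, K = design.G, design.n, design.K
    nt = np.full((boot_replicates, G * arms), n, dtype=float)
    rates = np.repeat(
        np.clip(rng.normal(design.alpha_start,
                           design.error_rate_spread * design.alpha_start,
                           boot_replicates), 1e-6, 1.0)[:, None],
        G * arms, axis=1)
    n1 = rng.binomial(n, rates).astype(float)
    if arms == 1:
        lam, _, _ = _batch.lrt_single_batch(n1, nt, K, config)
    else:
        lam, _, _ = _batch.lrt_joint_batch(n1[:, :G], nt[:, :G], K,
                                           n1[:, G:], nt[:, G:], K, config)
    return float(np.quantile(lam, 1.0 - gamma))


def estimate_power(design: SimDesign, test: str = "single-control",
                   gamma: float = 0.05, seed=0,
                   threshold: str = "auto",
                   config: EMConfig | None = None) -> PowerEstimate:
    """Estimate rejection power of a test under a case-control design.

    ``test``: "single-control" / "single-case" (the one-group polymorphism
    LRT applied to that arm), "joint" (two-group polymorphism LRT) or
    "association" (f1 != f0 LRT).  ``threshold``: "asymptotic",
    "bootstrap", or "auto" (asymptotic when G >= 20).  Returns the
    rejection fraction over ``design.replicates`` simulated replicates
    with its binomial standard error.
    """
    config = config or EMConfig()
    rng = np.random.default_rng(seed)
    batch = simulate_case_control_replicates(design, rng)
    K, G = design.K, design.G

    if test in ("single-control", "single-case"):
        arm = batch.control if test == "single-control" else batch.case
        lam, _, _ = _batch.lrt_single_batch(arm.n_minor.astype(float),
                                            arm.n_total.astype(float), K,
                                            config)
        mixture, arms = SINGLE_NULL, 1
    elif test == "joint":
        lam, _, _ = _batch.lrt_joint_batch(
            batch.case.n_minor.astype(float), batch.case.n_total.astype(float), K,
            batch.control.n_minor.astype(float), batch.control.n_total.astype(float),
            K, config)
        mixture, arms = JOINT_NULL, 2
    elif test == "association":
        lam, _, _, _ = _batch.association_lrt_batch(
            batch.case.n_minor.astype(float), batch.case.n_total.astype(float), K,
            batch.control.n_minor.astype(float), batch.control.n_total.astype(float),
            K, config)
        mixture, arms = None, 2
    else:
        raise ValueError(f"unknown test {test!r}")

    # The association statistic is an interior-null LRT; its chi2_1
    # asymptotics do not need the boundary bootstrap.
    use_boot = (mixture is not None
                and (threshold == "bootstrap"
                     or (threshold == "auto" and G < ASYMPTOTIC_MIN_POOLS)))
    if use_boot:
        t_gamma = _bootstrap_threshold_for_design(
            design, mixture, gamma, arms, rng, config)
        kind = "bootstrap"
    else:
        t_gamma = (float(chi2.isf(gamma, 1)) if mixture is None
                   else mixture_threshold(gamma, mixture))
        kind = "asymptotic"

    rej = lam > t_gamma
    p = float(rej.mean())
    se = math.sqrt(p * (1 - p) / len(rej)) if len(rej) > 1 else float("nan")
    return PowerEstimate(power=p, std_error=se, threshold=t_gamma,
                         threshold_kind=kind, replicates=len(rej))


def titv_ratio(variants: Iterable[tuple[str, str]]) -> float:
    """Transition/transversion ratio of (ref, alt) nucleotide pairs.

    Transitions are A<->G and C<->T; everything else among ACGT is a
    transversion.  Returns inf when there are no transversions.
    """
    ti = tv = 0
    for ref, alt in variants:
        ref, alt = ref.upper(), alt.upper()
        if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            raise ValueError(f"non-ACGT alleles ({ref!r}, {alt!r})")
        if ref == alt:
            raise ValueError("ref and alt must differ")
        if (ref, alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return float("inf")
    return ti / tv
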