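"""Generative simulator for pooled sequencing and case-control cohorts.

A simulated locus follows the model exactly: each of G pools draws a
carrier count C_g ~ Binomial(K, f), then n1_g ~ Binomial(n, p_{C_g}) minor
reads out of n.  Sequencing error rates vary from replicate to replicate:
each replicate draws its own alpha_i (= beta_i) from
Normal(alpha_start, (0.1 alpha_start)^2), truncated into [1e-6, 1].

Case-control cohorts sample whole individuals (K/2 per pool) so pools
contain complete genotypes.  Controls are Hardy-Weinberg at frequency f;
case genotype probabilities are the HWE probabilities reweighted by the
penetrances (g0, lambda g0, lambda^2 g0) of genotypes 00/01/11, so the
case-population allele frequency is f lambda / ((1 - f) + f lambda).

Reproducibility: a master seed spawns named substreams (per grid cell,
per replicate batch) via numpy SeedSequence spawn keys, so any cell can
be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterator, Sequence

import numpy as np

from .model import LocusData, PoolCounts

__all__ = [
    "SimDesign",
    "SimulatedLocus",
    "SimBatch",
    "CaseControlBatch",
    "F_GRID",
    "ALPHA_GRID",
    "N_GRID",
    "K_GRID",
    "G_GRID",
    "draw_error_rates",
    "simulate_replicates",
    "simulate_pool_locus",
    "simulate_case_control",
    "simulate_case_control_replicates",
    "generate_grid",
]

# Default study grid: 4 frequencies x 4 error rates x 2 depths x 3 pool
# sizes x 3 pool counts = 288 parameter combinations.
F_GRID = (0.001, 0.005, 0.01, 0.05)
ALPHA_GRID = (0.0005, 0.001, 0.005, 0.01)
N_GRID = (1000, 3000)
K_GRID = (50, 100, 200)
G_GRID = (10, 20, 50)

_RATE_FLOOR = 1e-6


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulation condition.

    f: true minor allele frequency; alpha_start: mean sequencing error
    rate (per-replicate rates are drawn around it with relative sd
    ``error_rate_spread``); n: reads per pool; K: chromosomes per pool;
    G: pools per group; replicates: number of independent loci;
    lambda_: per-allele relative risk and g0: baseline penetrance
    (case-control mode only).
    """

    f: float
    alpha_start: float
    n: int = 1000
    K: int = 100
    G: int = 10
    replicates: int = 1000
    error_rate_spread: float = 0.1
    lambda_: float = 1.0
    g0: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.alpha_start <= 0:
            raise ValueError("alpha_start must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")


@dataclass
class SimulatedLocus:
    """One simulated locus with its generating truths."""

    data: LocusData
    true_carrier_counts: np.ndarray     # C_g per pool
    true_error_rate: float              # alpha_i (= beta_i)

    @property
    def f_frac(self) -> float:
        """Realized fraction of carrier chromosomes, C / (K G)."""
        return float(self.true_carrier_counts.sum()
                     / (self.data.K * self.data.n_pools))


@dataclass
class SimBatch:
    """Replicated simulated loci in array form (R rows, G pools)."""

    design: SimDesign
    n_minor: np.ndarray       # (R, G)
    n_total: np.ndarray       # (R, G)
    carriers: np.ndarray      # (R, G)
    error_rates: np.ndarray   # (R,)

    @property
    def f_frac(self) -> np.ndarray:
        return self.carriers.sum(1) / (self.design.K * self.design.G)

    @property
    def naive(self) -> np.ndarray:
        """Per-replicate naive estimate f_avg = sum(n1_g)/sum(n_g)."""
        return self.n_minor.sum(1) / self.n_total.sum(1)

    def locus(self, i: int, locus_id=None) -> SimulatedLocus:
        pools = tuple(PoolCounts(int(t - m), int(m))
                      for m, t in zip(self.n_minor[i], self.n_total[i]))
        return SimulatedLocus(
            data=LocusData(pools, self.design.K,
                           locus_id=locus_id or f"sim:{i}"),
            true_carrier_counts=self.carriers[i].copy(),
            true_error_rate=float(self.error_rates[i]),
        )


@dataclass
class CaseControlBatch:
    case: SimBatch
    control: SimBatch


def draw_error_rates(alpha_start: float, spread: float, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw per-replicate error rates from Normal(alpha_start,
    (spread * alpha_start)^2), truncated into [1e-6, 1]."""
    if alpha_start <= 0:
        raise ValueError("alpha_start must be > 0")
    draws = rng.normal(alpha_start, spread * alpha_start, size=size)
    return np.clip(draws, _RATE_FLOOR, 1.0)


def _read_counts(carriers, K, n, rates, rng):
    """Minor-read counts given carrier counts; alpha_i = beta_i per row."""
    a = rates[:, None]
    p = (carriers / K) * (1.0 - a) + (1.0 - carriers / K) * a
    return rng.binomial(n, p).astype(np.int64)


def simulate_replicates(design: SimDesign, rng: np.random.Generator,
                        per_pool_rates: bool = False) -> SimBatch:
    """Simulate ``design.replicates`` independent loci of one group.

    By default one error rate alpha_i is drawn per replicate and shared
    by its pools; ``per_pool_rates`` draws a fresh rate per pool instead
    (the per-replicate record then holds the per-pool mean).
    """
    R, G, K, n = design.replicates, design.G, design.K, design.n
    rates = draw_error_rates(design.alpha_start, design.error_rate_spread,
                             R * G if per_pool_rates else R, rng)
    carriers = rng.binomial(K, design.f, size=(R, G))
    if per_pool_rates:
        rates = rates.reshape(R, G)
        p = (carriers / K) * (1.0 - rates) + (1.0 - carriers / K) * rates
        n1 = rng.binomial(n, p).astype(np.int64)
        rates = rates.mean(1)
    else:
        n1 = _read_counts(carriers, K, n, rates, rng)
    ntot = np.full((R, G), n, dtype=np.int64)
    return SimBatch(design=design, n_minor=n1, n_total=ntot,
                    carriers=carriers, error_rates=rates)


def simulate_pool_locus(design: SimDesign, error_rate: float,
                        rng: np.random.Generator) -> SimulatedLocus:
    """Simulate a single locus at a fixed error rate."""
    one = replace(design, replicates=1, alpha_start=error_rate,
                  error_rate_spread=0.0)
    return simulate_replicates(one, rng).locus(0)


def _case_genotype_probs(f: float, lambda_: float) -> np.ndarray:
    """Genotype distribution among affected individuals: HWE probabilities
    reweighted by penetrances (g0, lambda g0, lambda^2 g0); g0 cancels."""
    raw = np.array([(1 - f) ** 2, 2 * f * (1 - f) * lambda_,
                    f ** 2 * lambda_ ** 2])
    return raw / raw.sum()


def simulate_case_control_replicates(design: SimDesign,
                                     rng: np.random.Generator
                                     ) -> CaseControlBatch:
    """Simulate paired case/control pooled data for ``design.replicates`` loci.

    Each arm has G pools of K/2 individuals.  Control carrier counts are
    Binomial(K, f) (sum of K/2 HWE genotypes); case pools draw K/2
    genotypes from the penetrance-weighted distribution.  Both arms of a
    replicate share its error rate alpha_i.
    """
    if design.lambda_ <= 0:
        raise ValueError("case-control simulation needs lambda_ > 0")
    if design.K % 2:
        raise ValueError("case-control pools need an even K (whole individuals)")
    R, G, K, n = design.replicates, design.G, design.K, design.n
    rates = draw_error_rates(design.alpha_start, design.error_rate_spread,
                             R, rng)

    ctrl_carriers = rng.binomial(K, design.f, size=(R, G))
    geno = rng.multinomial(K // 2, _case_genotype_probs(design.f, design.lambda_),
                           size=(R, G))
    case_carriers = geno[..., 1] + 2 * geno[..., 2]

    ctrl_n1 = _read_counts(ctrl_carriers, K, n, rates, rng)
    case_n1 = _read_counts(case_carriers, K, n, rates, rng)
    ntot = np.full((R, G), n, dtype=np.int64)
    return CaseControlBatch(
        case=SimBatch(design=design, n_minor=case_n1, n_total=ntot.copy(),
                      carriers=case_carriers, error_rates=rates),
        control=SimBatch(design=design, n_minor=ctrl_n1, n_total=ntot,
                         carriers=ctrl_carriers, error_rates=rates),
    )


def simulate_case_control(design: SimDesign, rng: np.random.Generator
                          ) -> tuple[SimulatedLocus, SimulatedLocus]:
    """Single-locus case/control pair (case first)."""
    one = replace(design, replicates=1)
    batch = simulate_case_control_replicates(one, rng)
    return batch.case.locus(0, "sim:case"), batch.control.locus(0, "sim:control")


def cell_rng(seed, index: int) -> np.random.Generator:
    """Independent, reproducible substream for grid cell ``index``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_grid(f_values: Sequence[float] = F_GRID,
                  alpha_values: Sequence[float] = ALPHA_GRID,
                  n_values: Sequence[int] = N_GRID,
                  K_values: Sequence[int] = K_GRID,
                  G_values: Sequence[int] = G_GRID,
                  replicates: int = 1000,
                  seed=0) -> Iterator[tuple[SimDesign, SimBatch]]:
    """Lazily enumerate the Cartesian parameter grid with one SimBatch per
    cell; each cell gets its own seed substream so the enumeration is
    deterministic and any cell reproducible in isolation."""
    combos = list(product(f_values, alpha_values, n_values, K_values, G_values))
    for i, (f, a, n, K, G) in enumerate(combos):
        design = SimDesign(f=f, alpha_start=a, n=n, K=K, G=G,
                           replicates=replicates)
        yield design, simulate_replicates(design, cell_rng(seed, i))
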