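# Methods

## Model

A biallelic locus is sequenced in `G` untagged pools, each containing
`K` chromosomes (`K/2` diploid individuals).  The population minor
allele frequency is `f`; the number of carrier chromosomes in pool `g`
is latent, `C_g ~ Binomial(K, f)`.  Sequencing misreads a true major
allele as minor with probability `α` and a true minor as major with
probability `β`.  Given `C_g = k`, each of the `n_g` reads covering the
locus shows the minor allele with probability

    p_k = (k/K)(1 − β) + ((K − k)/K) α,

so the observed minor-read count is `n1_g ~ Binomial(n_g, p_k)` and the
marginal pool probability is a `(K+1)`-component binomial mixture with
weights `Binomial(k; K, f)`.  Pools are independent.  All likelihood
arithmetic is in log space with log-sum-exp over the mixture components
and log-gamma binomial coefficients (depths of several thousand reads
underflow otherwise).  Probability parameters are clamped `1e−12` away
from exact 0/1 inside evaluation only when a log of zero would occur;
stored estimates are never altered.

Assumptions: exactly two alleles; equal DNA contribution from every
individual in a pool; error rates constant across the reads of one
locus (they may differ between loci); no mapping error.

## Estimation

`(f, α, β)` are estimated by EM over the latent carrier counts and true
read states.  With `T11/T10/T01/T00` the expected read counts by (true,
observed) allele state, the M-step is `f ← E(C)/(GK)`,
`α ← T01/(T01+T00)`, `β ← T10/(T10+T11)`.  The E-step computes the
posterior over `k` per pool and per-read match expectations with the
kernel `E(I·r) ∝ (k/K)(1−β)·Bin(n1−1; n−1, p_k)`, rewritten through
`p_k·Bin(n1−1; n−1, p_k) = (n1/n)·Bin(n1; n, p_k)` so that the posterior
weights are reused.  Zero M-step denominators freeze the affected
parameter for that iteration.  The batched kernel vectorizes replicate
loci over the `(K+1)` carrier states and is bit-equivalent to the
per-pool scalar E-step (tested).

**Identifiability and the frequency bound.**  The likelihood is exactly
invariant under `(f, α, β) → (1−f, β, α)`; estimation therefore
constrains `f` to `[0, 0.5]` by default (configurable via
`f_upper_bound`).

**Multimodality and initialization.**  Beyond the global symmetry the
likelihood has *twin local modes* that trade carriers against error
along the lattice `p_k = α + k(1−α−β)/K`: a "signal" mode
(`f ≈` minor-read fraction, small `α`) and an "error" mode (small `f`,
`α ≈` the fraction), which fit the across-pool spread of minor-read
fractions almost equally well when `G` is small.  A grid search shows
the error mode can be the *global* maximum at `f = 5%, G = 10` even when
the data were generated from the signal mode, so a globally optimal
estimator would be badly biased there; the useful estimator is the EM
fixed point reached from a start that respects the scale of sequencing
error.  The default start is therefore:

* minor-read fraction `p̄ ≤ 3%`: a method-of-moments split — the
  across-pool variance of the pool fractions in excess of read-sampling
  noise estimates `f(1−f)/K` (carrier variation is the only term scaling
  with `K`); `f⁰` solves that quadratic and `α⁰ = p̄ − f⁰`, capped at
  1%, the error scale of current sequencing chemistry;
* `p̄ > 3%`: fractions far above any plausible error rate are treated as
  predominantly signal, `f⁰ = p̄`, `α⁰ = p̄/20`.

Convergence: absolute log-likelihood increase below `1e−8` or 500
iterations, both configurable.  The log-likelihood is nondecreasing at
every iteration (EM guarantee, asserted in tests).

**β handling.**  The default estimates `β` freely, matching the full
M-step.  At rare `f` very few reads descend from carrier chromosomes,
so `β` is nearly unidentifiable; its estimate wanders upward along the
ridge `f(1−β) ≈ const`, which inflates `f̂` by roughly `1/(1−β̂)`.
This inflation is part of the method's documented behavior at rare
frequencies (it is visible in the relative-error tables the evaluation
module reproduces).  A `tied` mode (`β = α`) removes the ridge and gives
an estimator whose bias is statistically indistinguishable from zero in
the recovery tests; use it when a point estimate of `f` alone is wanted.
`fixed` holds `β` at a supplied value.

**Restricted fits.**  Under `f = 0` the mixture collapses to its `k = 0`
term and `α̂ = Σn1_g/Σn_g` in closed form (`β` unidentifiable, reported
as NaN).  The shared-`f` case–control fit runs EM with a common
frequency and shared error rates across both groups; error rates are
shared between groups in both the restricted and unrestricted fits (a
per-group `K` is supported).

## Tests of polymorphism and association

`f = 0` lies on the boundary of the parameter space, so the LRT
statistic is not asymptotically `χ²`:

* joint test of `f0 = f1 = 0` over cases and controls:
  `Λ ~ ¼·I₀ + ½·χ²₁ + ¼·χ²₂`;
* single-group test of `f = 0`: `Λ ~ ½·I₀ + ½·χ²₁`,

where `I₀` is a point mass at zero.  The p-value at `Λ = 0` is defined
as 1 (conservative).  Because a cold-started alternative EM can stop a
hair below the closed-form null maximum, replicates violating the
nesting inequality are refit warm-started from the null solution, which
restores `Λ ≥ 0` by monotonicity; statistics are then clipped at zero
after asserting they exceed `−1e−6`.  With fewer than 20 pools the
asymptotic mixture is unreliable and a parametric bootstrap of the
fitted `f = 0` null supplies the rejection threshold (the default
policy; both are selectable).

The association statistic compares per-group frequencies `(f̂0, f̂1)`
against a shared `f̂`, both with shared error rates, and is referred to
`χ²₁` (an interior null).  A preliminary Fisher's exact p-value is
computed from EM-estimated minor-allele counts, rounded half away from
zero over the group's `G·K` chromosomes; it ignores estimation
uncertainty and is reported as approximate only.

## Simulator

The simulator draws from the model exactly: `C_g ~ Binomial(K, f)`,
`n1_g ~ Binomial(n, p_{C_g})`.  Per-replicate error rates are drawn from
`Normal(α_start, (0.1·α_start)²)` truncated to `[1e−6, 1]`, with
`β_i = α_i`; the stated dispersion is interpreted as a *standard
deviation* of `0.1·α_start` (a literal variance of `0.1·α_start` would
dwarf the mean and produce mostly negative rates).  One rate is shared
by all pools of a replicate by default (per-pool rates are available).
Case–control cohorts sample whole individuals, `K/2` per pool: controls
are Hardy–Weinberg at `f`; case genotype probabilities are the HWE
probabilities reweighted by penetrances `(g₀, λg₀, λ²g₀)` for 0/1/2
minor alleles (`g₀ = 0.01` by default; `g₀` cancels in the
normalization), giving case allele frequency `fλ/((1−f)+fλ)`.  A master
seed spawns named substreams per grid cell so any cell is reproducible
in isolation.  Default grids: `f ∈ {0.1, 0.5, 1, 5}%`,
`α ∈ {0.05, 0.1, 0.5, 1}%`, `n ∈ {1000, 3000}`, `K ∈ {50, 100, 200}`,
`G ∈ {10, 20, 50}` (288 combinations).

What the simulator does *not* emulate: read mapping and alignment
artifacts, base-quality structure within reads, uneven DNA contribution
between pooled individuals, linkage between loci, more than two
alleles.  Passing tests therefore demonstrate correctness of the
statistical machinery under the model, not robustness to real-data
artifacts upstream of the count table.

## Accuracy metrics

`MSE` measures squared error against the population `f`; `Cg` measures
it against the realized carrier fraction `f_frac = ΣC_g/(KG)` of the
same replicate.  For rare variants nearly all of the EM estimator's MSE
is the cohort sampling variance `f(1−f)/(KG)` (the `Cg` values are an
order of magnitude smaller), so `f̂_em` is best read as an estimate of
`f_frac`.  `RE = 100·|mean(f̂)−f|/f` measures bias.  Trimmed variants
drop `floor(R·κ/100)` estimates per tail (κ in percent, default 1)
before recomputing.  Power is the rejection fraction over simulated
case–control replicates at the γ = 0.05 threshold of the appropriate
null.  Ti/Tv counts A↔G and C↔T as transitions and reports infinity
when no transversions are called.

## Problem sizes

The packaged acceptance script uses 1000 replicates per grid cell for
the naive-estimator averages and the single-cell EM MSEs, 200 per cell
for the 18-cell EM sweeps, and 500 case–control replicates for power;
the pytest acceptance tests use 100–400 replicates with
correspondingly wider Monte-Carlo tolerances.

## Known limitations

* `β̂` is unreliable at rare `f` (see above); the default free-β
  estimator inherits a small upward bias in `f̂` there.
* The EM is a local optimizer by design; results at `f` near the
  signal/error ambiguity scale (minor fractions of 1–3% with error
  rates near 1%) depend on the documented starting policy.
* Pools are assumed to contain equal amounts of DNA per individual; an
  uneven-contribution (Dirichlet) extension is out of scope.
* The Fisher p-value on estimated counts is approximate by
  construction; use the likelihood-ratio p-value for inference.
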