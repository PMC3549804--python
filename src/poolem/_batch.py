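"""Vectorized EM and likelihood-ratio kernels.

Every function here operates on count arrays of shape (R, G): R independent
replicate loci, G pools each, a single pool size K per call.  Parameter
vectors have shape (R,).  These kernels back the public scalar API in
``em.py`` / ``calling.py`` (R = 1) and the simulation-scale loops in
``evaluation.py`` and ``scripts/acceptance.py``.

Probability parameters are clamped a tiny margin off 0/1 at evaluation time
only; the parameter arrays carried between iterations are the raw M-step
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy
from scipy.stats import chi2

_EVAL_CLAMP = 1e-12
# LRT statistics may dip this far below zero from finite EM convergence;
# anything lower is a genuine nesting violation and raises.
LRT_SLACK = 1e-6


def log_comb(n, k):
    """log C(n, k) via log-gamma; safe for n in the thousands."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


@dataclass
class EStepSums:
    """Per-replicate expected sufficient statistics from one E-step."""

    ec_pool: np.ndarray     # (R, G) posterior mean carrier count per pool
    ec: np.ndarray          # (R,)   total expected carriers E(C)
    t11: np.ndarray         # (R,)   true-minor read observed minor
    t10: np.ndarray         # (R,)   true-minor read observed major
    t01: np.ndarray         # (R,)   true-major read observed minor
    t00: np.ndarray         # (R,)   true-major read observed major
    loglik: np.ndarray      # (R,)   observed-data log-likelihood


def estep_sums(n1, n0, K, f, alpha, beta, comb_read, comb_k) -> EStepSums:
    """One E-step over the (K+1) latent carrier states for all replicates.

    The T expectations use the per-read kernels
    E(I r)     ∝ (k/K)(1-β) Bin(n1-1; n-1, p_k)
    E(I(1-r))  ∝ (k/K)β     Bin(n1;   n-1, p_k)
    E((1-I)r)  ∝ ((K-k)/K)α Bin(n1-1; n-1, p_k)
    E((1-I)(1-r)) ∝ ((K-k)/K)(1-α) Bin(n1; n-1, p_k)
    rewritten through p_k Bin(n1-1; n-1, p_k) = (n1/n) Bin(n1; n, p_k) so the
    posterior weights w_k can be reused: e.g. T11_g = n1_g Σ_k w_k (k/K)(1-β)/p_k.
    """
    k = np.arange(K + 1, dtype=float)
    fe = np.clip(f, _EVAL_CLAMP, 1 - _EVAL_CLAMP)[:, None]
    ae = np.clip(alpha, _EVAL_CLAMP, 1 - _EVAL_CLAMP)[:, None]
    be = np.clip(beta, _EVAL_CLAMP, 1 - _EVAL_CLAMP)[:, None]
    kk = k / K
    pk = kk * (1.0 - be) + (1.0 - kk) * ae                       # (R, K+1), in (0,1)
    log_prior = comb_k + xlogy(k, fe) + xlogy(K - k, 1.0 - fe)   # (R, K+1)
    log_read = (comb_read[:, :, None]
                + xlogy(n1[:, :, None], pk[:, None, :])
                + xlogy(n0[:, :, None], 1.0 - pk[:, None, :]))   # (R, G, K+1)
    log_w = log_read + log_prior[:, None, :]
    ll_pool = logsumexp(log_w, axis=2)                           # (R, G)
    w = np.exp(log_w - ll_pool[:, :, None])

    ec_pool = w @ k                                              # (R, G)
    t11 = (n1 * np.einsum("rgk,rk->rg", w, kk * (1.0 - be) / pk)).sum(1)
    t01 = (n1 * np.einsum("rgk,rk->rg", w, (1.0 - kk) * ae / pk)).sum(1)
    t10 = (n0 * np.einsum("rgk,rk->rg", w, kk * be / (1.0 - pk))).sum(1)
    t00 = (n0 * np.einsum("rgk,rk->rg", w, (1.0 - kk) * (1.0 - ae) / (1.0 - pk))).sum(1)
    return EStepSums(ec_pool=ec_pool, ec=ec_pool.sum(1),
                     t11=t11, t10=t10, t01=t01, t00=t00,
                     loglik=ll_pool.sum(1))


@dataclass
class BatchFit:
    f: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    loglik: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    ec_pool: np.ndarray | None = None
    history: list[np.ndarray] = field(default_factory=list)


def moment_init(n1, ntot, K):
    """Method-of-moments split of the minor-read fraction into (f0, alpha0).

    The mean pool fraction estimates f + alpha (to first order), while the
    across-pool variance in excess of read-sampling noise estimates
    f(1-f)/K — carrier-count variation between pools is the only model
    term that scales with K.  Solving f(1-f) = K * excess (small root)
    separates a true-signal basin (f approx the fraction, alpha small)
    from a pure-error basin (f approx 0, alpha approx the fraction), which
    the likelihood alone can leave merged for small G.
    """
    tot = np.maximum(ntot.sum(1), 1.0)
    pbar = n1.sum(1) / tot
    G = n1.shape[1]
    if G >= 2:
        frac = np.divide(n1, ntot, out=np.zeros_like(n1, dtype=float),
                         where=ntot > 0)
        s2 = frac.var(axis=1, ddof=1)
        nbar = ntot.mean(1)
        excess = np.maximum(s2 - pbar * (1.0 - pbar) / np.maximum(nbar, 1.0),
                            0.0)
        q = np.minimum(K * excess, 0.25)
        f0 = (1.0 - np.sqrt(1.0 - 4.0 * q)) / 2.0
    else:
        f0 = pbar.copy()
    alpha0 = np.maximum(pbar - f0, 1e-4)
    return f0, alpha0


# Scale of sequencing error plausible for current NGS chemistry; a
# minor-read fraction clearly above it is treated as predominantly signal
# when choosing the EM starting point (the likelihood has twin modes that
# trade carriers against error, and the start decides which one EM refines).
ERROR_SCALE = 0.01
SIGNAL_FRACTION = 0.03


def hybrid_start(n1, ntot, K):
    """Starting point (f0, alpha0) for the EM.

    Above SIGNAL_FRACTION the minor-read fraction itself is the frequency
    start and the error rate starts small; below it, the moment split
    decides how much of the fraction is error, capped at ERROR_SCALE.
    """
    tot = np.maximum(ntot.sum(1), 1.0)
    pbar = n1.sum(1) / tot
    f0m, _ = moment_init(n1, ntot, K)
    signal = pbar > SIGNAL_FRACTION
    f0 = np.where(signal, pbar, f0m)
    alpha0 = np.where(signal, np.maximum(pbar / 20.0, 1e-4),
                      np.clip(pbar - f0m, 1e-4, ERROR_SCALE))
    return f0, alpha0


def _init_params(n1, ntot, K, config, fix_f):
    f0, alpha = hybrid_start(n1, ntot, K)
    if fix_f is None:
        f = np.clip(f0, 1e-6, config.f_upper_bound)
    else:
        f = np.broadcast_to(np.asarray(fix_f, dtype=float), (n1.shape[0],)).copy()
    if config.estimate_beta == "fixed":
        beta = np.full_like(alpha, config.beta_value)
    else:
        beta = alpha.copy()
    return f, alpha, beta


def _update_errors(alpha, beta, s: EStepSums, idx, mode, beta_value):
    """M-step error-rate updates on the rows ``idx``; zero denominators
    freeze the affected parameter for the iteration.  Updates are kept a
    hair inside [0, 1) — a degenerate posterior (e.g. no observed minor
    reads at all) would otherwise push an error rate to exactly 1."""
    hi = 1.0 - 1e-10
    if mode == "tied":
        num = s.t01 + s.t10
        den = num + s.t00 + s.t11
        ok = den > 0
        upd = np.where(ok, np.minimum(num / np.where(ok, den, 1.0), hi),
                       alpha[idx])
        alpha[idx] = upd
        beta[idx] = upd
    else:
        den_a = s.t01 + s.t00
        ok = den_a > 0
        alpha[idx] = np.where(ok, np.minimum(s.t01 / np.where(ok, den_a, 1.0),
                                             hi), alpha[idx])
        if mode == "free":
            den_b = s.t10 + s.t11
            ok = den_b > 0
            beta[idx] = np.where(ok, np.minimum(s.t10 / np.where(ok, den_b, 1.0),
                                                hi), beta[idx])
        # mode == "fixed": beta stays at beta_value


def em_single(n1, ntot, K, config, fix_f=None, init=None) -> BatchFit:
    """Batched EM for one group of pools; each row is an independent locus.

    ``init``: optional (f0, alpha0, beta0) arrays overriding the default
    starting point (used to warm-start nested fits).
    """
    n1 = np.asarray(n1, dtype=float)
    ntot = np.asarray(ntot, dtype=float)
    R, G = n1.shape
    n0 = ntot - n1
    comb_read = log_comb(ntot, n1)
    comb_k = log_comb(K, np.arange(K + 1))
    if init is None:
        f, alpha, beta = _init_params(n1, ntot, K, config, fix_f)
    else:
        f, alpha, beta = (np.array(x, dtype=float) for x in init)

    prev = np.full(R, -np.inf)
    ll = np.full(R, -np.inf)
    iters = np.zeros(R, dtype=int)
    conv = np.zeros(R, dtype=bool)
    ec_pool = np.zeros((R, G))
    history: list[np.ndarray] = []
    active = np.arange(R)

    for _ in range(config.max_iterations):
        s = estep_sums(n1[active], n0[active], K,
                       f[active], alpha[active], beta[active],
                       comb_read[active], comb_k)
        if not np.all(np.isfinite(s.loglik)):
            bad = active[~np.isfinite(s.loglik)][0]
            raise FloatingPointError(
                f"non-finite likelihood at replicate {bad} "
                f"(counts n1={n1[bad]}, n={ntot[bad]})")
        ll[active] = s.loglik
        ec_pool[active] = s.ec_pool
        iters[active] += 1
        if config.track_history:
            history.append(ll.copy())
        done = (s.loglik - prev[active]) < config.tolerance
        conv[active[done]] = True
        prev[active] = s.loglik
        keep = ~done
        nxt = active[keep]
        if nxt.size == 0:
            break
        sk = EStepSums(ec_pool=s.ec_pool[keep], ec=s.ec[keep],
                       t11=s.t11[keep], t10=s.t10[keep],
                       t01=s.t01[keep], t00=s.t00[keep],
                       loglik=s.loglik[keep])
        if fix_f is None:
            f[nxt] = np.clip(sk.ec / (G * K), 0.0, config.f_upper_bound)
        _update_errors(alpha, beta, sk, nxt, config.estimate_beta,
                       config.beta_value)
        active = nxt

    return BatchFit(f=f, alpha=alpha, beta=beta, loglik=ll,
                    iterations=iters, converged=conv, ec_pool=ec_pool,
                    history=history)


@dataclass
class TwoGroupFit:
    f_a: np.ndarray
    f_b: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    loglik: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray


def em_two_group(n1a, nta, Ka, n1b, ntb, Kb, config,
                 share_f: bool = False, init=None) -> TwoGroupFit:
    """Batched EM over two pool groups (e.g. cases and controls).

    Error rates (alpha, beta) are always shared across the groups; the
    allele frequency is per-group unless ``share_f``.  Pool sizes Ka/Kb
    may differ.
    """
    n1a = np.asarray(n1a, dtype=float); nta = np.asarray(nta, dtype=float)
    n1b = np.asarray(n1b, dtype=float); ntb = np.asarray(ntb, dtype=float)
    R, Ga = n1a.shape
    Gb = n1b.shape[1]
    n0a, n0b = nta - n1a, ntb - n1b
    comb_a = log_comb(nta, n1a); comb_b = log_comb(ntb, n1b)
    ck_a = log_comb(Ka, np.arange(Ka + 1))
    ck_b = log_comb(Kb, np.arange(Kb + 1))

    if init is not None:
        fa, fb, alpha, beta = (np.array(x, dtype=float) for x in init)
    else:
        f0a, al_a = hybrid_start(n1a, nta, Ka)
        f0b, al_b = hybrid_start(n1b, ntb, Kb)
        if share_f:
            wa = Ga * Ka / (Ga * Ka + Gb * Kb)
            fa = np.clip(wa * f0a + (1 - wa) * f0b, 1e-6, config.f_upper_bound)
            fb = fa.copy()
        else:
            fa = np.clip(f0a, 1e-6, config.f_upper_bound)
            fb = np.clip(f0b, 1e-6, config.f_upper_bound)
        alpha = np.maximum((al_a + al_b) / 2.0, 1e-4)
        beta = (np.full_like(alpha, config.beta_value)
                if config.estimate_beta == "fixed" else alpha.copy())

    prev = np.full(R, -np.inf)
    ll = np.full(R, -np.inf)
    iters = np.zeros(R, dtype=int)
    conv = np.zeros(R, dtype=bool)
    active = np.arange(R)

    for _ in range(config.max_iterations):
        sa = estep_sums(n1a[active], n0a[active], Ka, fa[active],
                        alpha[active], beta[active], comb_a[active], ck_a)
        sb = estep_sums(n1b[active], n0b[active], Kb, fb[active],
                        alpha[active], beta[active], comb_b[active], ck_b)
        cur = sa.loglik + sb.loglik
        if not np.all(np.isfinite(cur)):
            bad = active[~np.isfinite(cur)][0]
            raise FloatingPointError(f"non-finite likelihood at replicate {bad}")
        ll[active] = cur
        iters[active] += 1
        done = (cur - prev[active]) < config.tolerance
        conv[active[done]] = True
        prev[active] = cur
        keep = ~done
        nxt = active[keep]
        if nxt.size == 0:
            break
        if share_f:
            fs = np.clip((sa.ec[keep] + sb.ec[keep]) / (Ga * Ka + Gb * Kb),
                         0.0, config.f_upper_bound)
            fa[nxt] = fs
            fb[nxt] = fs
        else:
            fa[nxt] = np.clip(sa.ec[keep] / (Ga * Ka), 0.0, config.f_upper_bound)
            fb[nxt] = np.clip(sb.ec[keep] / (Gb * Kb), 0.0, config.f_upper_bound)
        pooled = EStepSums(
            ec_pool=None, ec=None,
            t11=sa.t11[keep] + sb.t11[keep], t10=sa.t10[keep] + sb.t10[keep],
            t01=sa.t01[keep] + sb.t01[keep], t00=sa.t00[keep] + sb.t00[keep],
            loglik=None)
        _update_errors(alpha, beta, pooled, nxt, config.estimate_beta,
                       config.beta_value)
        active = nxt

    return TwoGroupFit(f_a=fa, f_b=fb, alpha=alpha, beta=beta, loglik=ll,
                       iterations=iters, converged=conv)


def null_loglik(n1, ntot):
    """Closed-form MLE under f = 0: counts are pure error, n1_g ~ Bin(n_g, α).

    Returns (alpha_hat, loglik), each shape (R,).
    """
    n1 = np.asarray(n1, dtype=float)
    ntot = np.asarray(ntot, dtype=float)
    tot = ntot.sum(1)
    if np.any(tot <= 0):
        raise ValueError("f=0 fit undefined: a replicate has no reads")
    a = n1.sum(1) / tot
    n0 = ntot - n1
    ll = (log_comb(ntot, n1) + xlogy(n1, a[:, None])
          + xlogy(n0, 1.0 - a[:, None])).sum(1)
    return a, ll


def clip_lrt(lam):
    """Assert the nesting inequality up to numerical slack, then clip at 0."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < -LRT_SLACK):
        raise FloatingPointError(
            f"negative LRT statistic {lam.min():.3g} beyond numerical slack")
    return np.clip(lam, 0.0, None)


def mixture_sf(lam, w0, w1, w2):
    """Survival function of w0·I0 + w1·χ²₁ + w2·χ²₂ evaluated at lam ≥ 0.

    The point mass contributes only at 0, where the p-value is 1.
    """
    lam = np.asarray(lam, dtype=float)
    p = w1 * chi2.sf(lam, 1) + w2 * chi2.sf(lam, 2)
    p = np.where(lam <= 0, 1.0, p)
    return p if p.ndim else float(p)


def em_single_safe(n1, ntot, K, config):
    """EM fit guaranteed not to fall below the f = 0 boundary maximum.

    Replicates whose cold-started fit ends below the closed-form f = 0
    solution (a local-mode stall) are refit warm-started from that
    boundary point; EM monotonicity then restores the nesting inequality
    l(fit) >= l(f=0).  Returns (fit, null_alpha, null_loglik).
    """
    n1 = np.asarray(n1, dtype=float)
    ntot = np.asarray(ntot, dtype=float)
    fit = em_single(n1, ntot, K, config)
    a0, ll0 = null_loglik(n1, ntot)
    short = fit.loglik < ll0
    if np.any(short):
        a_s = np.clip(a0[short], 1e-10, 1.0 - 1e-10)
        warm = em_single(n1[short], ntot[short], K, config,
                         init=(np.full(int(short.sum()), 1e-9), a_s,
                               a_s.copy()))
        better = warm.loglik > fit.loglik[short]
        idx = np.flatnonzero(short)[better]
        fit.loglik[idx] = warm.loglik[better]
        fit.f[idx] = warm.f[better]
        fit.alpha[idx] = warm.alpha[better]
        fit.beta[idx] = warm.beta[better]
        fit.iterations[idx] += warm.iterations[better]
        fit.converged[idx] = warm.converged[better]
        if fit.ec_pool is not None and warm.ec_pool is not None:
            fit.ec_pool[idx] = warm.ec_pool[better]
    return fit, a0, ll0


def lrt_single_batch(n1, ntot, K, config):
    """Λ_i = 2(l_{f≠0} − l_{f=0}) per replicate, with its (½I0 + ½χ²₁) p-value."""
    fit, _, ll0 = em_single_safe(n1, ntot, K, config)
    lam = clip_lrt(2.0 * (fit.loglik - ll0))
    return lam, mixture_sf(lam, 0.5, 0.5, 0.0), fit


def _warm_fix_two_group(alt, floor_ll, make_init, n1a, nta, Ka, n1b, ntb, Kb,
                        config):
    """Refit rows whose alternative fell below a nested fit's likelihood."""
    short = alt.loglik < floor_ll
    if not np.any(short):
        return alt
    warm = em_two_group(n1a[short], nta[short], Ka, n1b[short], ntb[short],
                        Kb, config, share_f=False, init=make_init(short))
    better = warm.loglik > alt.loglik[short]
    idx = np.flatnonzero(short)[better]
    for attr in ("loglik", "f_a", "f_b", "alpha", "beta"):
        getattr(alt, attr)[idx] = getattr(warm, attr)[better]
    return alt


def lrt_joint_batch(n1a, nta, Ka, n1b, ntb, Kb, config):
    """Joint Λ = 2(l_{f≠0} − l_{f=0}) over both groups; (¼I0+½χ²₁+¼χ²₂) null."""
    n1a = np.asarray(n1a, dtype=float); nta = np.asarray(nta, dtype=float)
    n1b = np.asarray(n1b, dtype=float); ntb = np.asarray(ntb, dtype=float)
    alt = em_two_group(n1a, nta, Ka, n1b, ntb, Kb, config, share_f=False)
    a0, ll0 = null_loglik(np.concatenate([n1a, n1b], axis=1),
                          np.concatenate([nta, ntb], axis=1))

    def null_init(short):
        m = int(short.sum())
        a_s = np.maximum(a0[short], 1e-10)
        return (np.full(m, 1e-9), np.full(m, 1e-9), a_s, a_s.copy())

    alt = _warm_fix_two_group(alt, ll0, null_init, n1a, nta, Ka, n1b, ntb,
                              Kb, config)
    lam = clip_lrt(2.0 * (alt.loglik - ll0))
    return lam, mixture_sf(lam, 0.25, 0.5, 0.25), alt


def association_lrt_batch(n1a, nta, Ka, n1b, ntb, Kb, config):
    """Λ_assoc = 2(l(f̂a, f̂b, α̂, β̂) − l(f̂ shared, α̂, β̂)); χ²₁ p-value."""
    n1a = np.asarray(n1a, dtype=float); nta = np.asarray(nta, dtype=float)
    n1b = np.asarray(n1b, dtype=float); ntb = np.asarray(ntb, dtype=float)
    alt = em_two_group(n1a, nta, Ka, n1b, ntb, Kb, config, share_f=False)
    nul = em_two_group(n1a, nta, Ka, n1b, ntb, Kb, config, share_f=True)

    def shared_init(short):
        return (nul.f_a[short], nul.f_b[short], nul.alpha[short],
                nul.beta[short])

    alt = _warm_fix_two_group(alt, nul.loglik, shared_init, n1a, nta, Ka,
                              n1b, ntb, Kb, config)
    lam = clip_lrt(2.0 * (alt.loglik - nul.loglik))
    return lam, chi2.sf(lam, 1), alt, nul
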