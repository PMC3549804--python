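"""Case-control association testing at called SNPs.

The association statistic compares the unrestricted fit (separate case
and control frequencies f1, f0 with shared error rates) against the
restricted fit (a single shared frequency):

    Lambda = 2 [ l(f0_hat, f1_hat, alpha_hat, beta_hat)
                 - l(f_hat, alpha_hat, beta_hat) ]  ~  chi2_1 under H0.

A preliminary Fisher's exact p-value on the EM-estimated minor-allele
counts is also provided; it ignores the estimation uncertainty of the
frequencies and is documented as approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import fisher_exact

from . import _batch
from .em import EMConfig, fit_case_control
from .model import LocusData

__all__ = ["AssociationResult", "association_lrt", "fisher_preliminary"]


@dataclass
class AssociationResult:
    locus_id: object
    f_control: float            # f0_hat
    f_case: float               # f1_hat
    n_control: int              # estimated minor-allele count, controls
    n_case: int                 # estimated minor-allele count, cases
    lrt_statistic: float
    lrt_p_value: float
    fisher_p_value: float
    alpha: float
    beta: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def association_lrt(case_locus: LocusData, control_locus: LocusData,
                    config: EMConfig | None = None) -> AssociationResult:
    """Likelihood-ratio association test for f1 != f0 at one locus."""
    config = config or EMConfig()
    if int(case_locus.n_total.sum()) == 0 or int(control_locus.n_total.sum()) == 0:
        raise ValueError("association test needs reads in both groups")
    lam_arr, pval_arr, alt, _ = _batch.association_lrt_batch(
        case_locus.n_minor[None, :].astype(float),
        case_locus.n_total[None, :].astype(float), case_locus.K,
        control_locus.n_minor[None, :].astype(float),
        control_locus.n_total[None, :].astype(float), control_locus.K, config)
    lam = float(lam_arr[0])
    chrom_case = case_locus.n_pools * case_locus.K
    chrom_ctrl = control_locus.n_pools * control_locus.K
    f_case, f_ctrl = float(alt.f_a[0]), float(alt.f_b[0])
    n_case = _round_half_away(f_case * chrom_case)
    n_ctrl = _round_half_away(f_ctrl * chrom_ctrl)
    fisher_p = _fisher_from_counts(n_case, chrom_case, n_ctrl, chrom_ctrl)
    return AssociationResult(
        locus_id=case_locus.locus_id or control_locus.locus_id,
        f_control=f_ctrl, f_case=f_case,
        n_control=n_ctrl, n_case=n_case,
        lrt_statistic=lam, lrt_p_value=float(pval_arr[0]),
        fisher_p_value=fisher_p, alpha=float(alt.alpha[0]),
        beta=float(alt.beta[0]),
    )


def _fisher_from_counts(n_case: int, chrom_case: int,
                        n_ctrl: int, chrom_ctrl: int) -> float:
    table = [[n_case, chrom_case - n_case], [n_ctrl, chrom_ctrl - n_ctrl]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def fisher_preliminary(case_locus: LocusData, control_locus: LocusData,
                       chromosomes_case: int | None = None,
                       chromosomes_control: int | None = None,
                       config: EMConfig | None = None) -> float:
    """Preliminary two-sided Fisher's exact p-value on estimated counts.

    The EM frequency estimates for each group are converted to minor-allele
    counts by rounding f_hat x (total chromosomes in the group), half away
    from zero, and the resulting 2x2 table is tested exactly.  Because the
    counts are estimates, not observations, this p-value is approximate;
    prefer :func:`association_lrt` for inference.
    """
    config = config or EMConfig()
    chrom_case = chromosomes_case or case_locus.n_pools * case_locus.K
    chrom_ctrl = chromosomes_control or control_locus.n_pools * control_locus.K
    fit = fit_case_control(case_locus, control_locus, share_f=False,
                           config=config)
    n_case = _round_half_away(fit.f_case * chrom_case)
    n_ctrl = _round_half_away(fit.f_control * chrom_ctrl)
    return _fisher_from_counts(n_case, chrom_case, n_ctrl, chrom_ctrl)
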