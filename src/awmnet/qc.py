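"""Marker and sample quality control.

Filters follow standard SNP-chip practice: sample call rate, SNP call
rate, minor allele frequency, and Hardy-Weinberg equilibrium, applied in
that order so the HWE test runs on the cleaned sample set. Missing
genotypes surviving QC are left missing here; downstream stages mean-impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .containers import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "hwe_test", "apply_qc", "EmptyPanelError"]


class EmptyPanelError(RuntimeError):
    """All SNPs (or all samples) were removed by QC."""


@dataclass
class QCThresholds:
    hwe_p_min: float = 1e-4
    maf_min: float = 0.05
    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "snp_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_by_filter: dict[str, list[str]] = field(default_factory=dict)
    snp_maf: dict[str, float] = field(default_factory=dict)
    snp_call_rate: dict[str, float] = field(default_factory=dict)
    snp_hwe_p: dict[str, float] = field(default_factory=dict)

    def check_counts(self) -> bool:
        snp_removed = set()
        for f in ("snp_call_rate", "maf", "hwe"):
            snp_removed |= set(self.removed_by_filter.get(f, []))
        sample_removed = set(self.removed_by_filter.get("sample_call_rate", []))
        return (
            self.n_snps_out + len(snp_removed) == self.n_snps_in
            and self.n_samples_out + len(sample_removed) == self.n_samples_in
        )


def _log_hwe_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """log P(n_het heterozygotes | n diploids, n_rare rare-allele copies)
    under HWE: the Levene-Haldane distribution."""
    n_common = 2 * n - n_rare
    hom_rare = (n_rare - n_het) // 2
    hom_common = n - n_het - hom_rare
    return (
        lgamma(n + 1)
        - lgamma(hom_rare + 1)
        - lgamma(n_het + 1)
        - lgamma(hom_common + 1)
        + n_het * log(2.0)
        + lgamma(n_rare + 1)
        + lgamma(n_common + 1)
        - lgamma(2 * n + 1)
    )


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``exact`` sums Levene-Haldane probabilities of all heterozygote counts
    (same parity, fixed allele counts) no more probable than the observed
    one; ``chi2`` is the 1-df goodness-of-fit test against expected HWE
    counts. Monomorphic SNPs return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0  # monomorphic: flagged trivially in HWE
    if method == "chi2":
        p = n_A / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
        stat = ((obs - exp) ** 2 / exp).sum()
        return float(chi2_dist.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")
    n_rare = min(n_a, n_A)
    hets = range(n_rare % 2, n_rare + 1, 2)
    logps = {h: _log_hwe_het_prob(h, n_rare, n) for h in hets}
    obs_lp = logps[n_Aa]
    # sum P(h) over all h with P(h) <= P(observed); tiny slack for ties
    total = sum(np.exp(lp) for lp in logps.values() if lp <= obs_lp + 1e-12)
    return float(min(total, 1.0))


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples then SNPs; order: sample call rate -> SNP call rate
    -> MAF -> HWE (computed on surviving samples only)."""
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_snps_out=0,
        n_samples_in=genotypes.n_animals,
        n_samples_out=0,
    )

    sample_cr = genotypes.call_rate_samples()
    keep_samples = np.nonzero(sample_cr >= thresholds.sample_call_rate_min)[0]
    report.removed_by_filter["sample_call_rate"] = [
        genotypes.sample_ids[i]
        for i in np.nonzero(sample_cr < thresholds.sample_call_rate_min)[0]
    ]
    if len(keep_samples) == 0:
        raise EmptyPanelError("sample call-rate filter removed every sample")
    gm = genotypes.subset(sample_idx=keep_samples)

    snp_ids = np.array(gm.snp_ids)
    cr = gm.call_rate_snps()
    fail_cr = cr < thresholds.snp_call_rate_min
    report.removed_by_filter["snp_call_rate"] = snp_ids[fail_cr].tolist()

    with np.errstate(invalid="ignore"):
        maf = gm.minor_allele_frequencies()
    fail_maf = (~fail_cr) & (np.isnan(maf) | (maf < thresholds.maf_min))
    report.removed_by_filter["maf"] = snp_ids[fail_maf].tolist()

    candidate = ~(fail_cr | fail_maf)
    hwe_p = np.ones(gm.n_snps)
    for j in np.nonzero(candidate)[0]:
        col = gm.genotypes[:, j]
        col = col[~np.isnan(col)]
        n_aa_hi = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_aa_lo = int((col == 0).sum())
        hwe_p[j] = hwe_test(n_aa_lo, n_het, n_aa_hi, method=hwe_method)
    fail_hwe = candidate & (hwe_p < thresholds.hwe_p_min)
    report.removed_by_filter["hwe"] = snp_ids[fail_hwe].tolist()

    keep = candidate & ~fail_hwe
    if not keep.any():
        raise EmptyPanelError("QC removed every SNP (empty panel)")
    out = gm.subset(snp_idx=np.nonzero(keep)[0])

    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_animals
    report.snp_maf = dict(zip(snp_ids.tolist(), np.nan_to_num(maf, nan=0.0).tolist()))
    report.snp_call_rate = dict(zip(snp_ids.tolist(), cr.tolist()))
    report.snp_hwe_p = dict(zip(snp_ids.tolist(), hwe_p.tolist()))
    return out, report
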