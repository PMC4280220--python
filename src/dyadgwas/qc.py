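"""Genotype quality control.

Filters follow the usual case-control GWAS recipe: drop samples with a
high missing fraction, then SNPs that are rare or poorly genotyped
(single combined tally), then SNPs violating Hardy-Weinberg equilibrium
among controls (exact test).  The report's arithmetic is additive so the
retained counts always reconcile with the removal tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammaln

from .geno_io import GenotypeDataset

__all__ = ["QCThresholds", "QCReport", "compute_maf", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults are standard GWAS practice."""

    max_sample_missing: float = 0.10
    max_snp_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-4

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class QCReport:
    n_snps_input: int
    n_samples_input: int
    n_samples_removed_missing: int
    n_snps_removed_maf_or_missing: int
    n_snps_removed_hwe: int

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_input - self.n_samples_removed_missing

    @property
    def n_snps_retained(self) -> int:
        return (self.n_snps_input - self.n_snps_removed_maf_or_missing
                - self.n_snps_removed_hwe)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_samples_retained"] = self.n_samples_retained
        d["n_snps_retained"] = self.n_snps_retained
        return d


def compute_maf(dosages: np.ndarray) -> tuple[float, bool]:
    """Minor-allele frequency of a dosage vector, with orientation flag.

    Returns ``(maf, flipped)`` where ``flipped`` is True when the stored
    dosage counts the *major* allele (frequency > 0.5) and the value was
    re-oriented.  Missing entries (nan) are ignored.
    """
    d = np.asarray(dosages, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("minor-allele frequency undefined: all genotypes missing")
    f = float(d.sum()) / (2 * d.size)
    if f > 0.5:
        return 1.0 - f, True
    return f, False


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    probable than the observed one (Wigginton-style convention).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    # all attainable het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (hets * np.log(2) + gammaln(n + 1)
            - gammaln(hets + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeDataset, QCReport]:
    """Apply sample call-rate, SNP MAF/call-rate and control-HWE filters.

    SNP MAF and missingness removals share a single combined tally.  The
    HWE exact test is computed among remaining controls only.
    """
    d = dataset.dosage
    n, m = d.shape
    miss = np.isnan(d)

    sample_keep = miss.mean(axis=1) <= thresholds.max_sample_missing
    d1 = d[sample_keep]
    miss1 = miss[sample_keep]
    pheno1 = dataset.phenotype[sample_keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        freq = np.nanmean(d1, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    snp_miss = miss1.mean(axis=0) if d1.shape[0] else np.ones(m)
    bad_snp = (snp_miss > thresholds.max_snp_missing) | ~(maf >= thresholds.min_maf)

    controls = pheno1 == 0
    hwe_bad = np.zeros(m, bool)
    for j in np.flatnonzero(~bad_snp):
        col = d1[controls, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = np.bincount(col.astype(int), minlength=3)
        # orient: hom-major first (test is symmetric in the labels)
        p = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
        hwe_bad[j] = p < thresholds.hwe_alpha

    report = QCReport(
        n_snps_input=m,
        n_samples_input=n,
        n_samples_removed_missing=int((~sample_keep).sum()),
        n_snps_removed_maf_or_missing=int(bad_snp.sum()),
        n_snps_removed_hwe=int(hwe_bad.sum()),
    )
    filtered = dataset.subset(sample_mask=sample_keep, variant_mask=~(bad_snp | hwe_bad))
    if filtered.n_variants == 0 or filtered.n_samples == 0:
        warnings.warn("QC removed every sample or every SNP", stacklevel=2)
    return filtered, report
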