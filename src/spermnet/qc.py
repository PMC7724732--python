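"""Genotype quality control: call-rate / MAF / HWE / missingness filters,
autosome restriction and pairwise linkage disequilibrium.

Filters mirror the usual array-genotyping defaults: samples with a call rate
below 96% are dropped, then SNPs with minor allele frequency below 0.05, a
Hardy-Weinberg exact P-value at or below 1e-3, more than 5% missing calls, or
a non-autosomal map position.  Boundary handling is strict in the sense that
only values *worse than* the threshold are removed (a call rate of exactly
0.96 or a MAF of exactly 0.05 is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["QcThresholds", "QcReport", "hwe_exact_test", "apply_qc", "ld_r2"]

#: chromosome labels treated as non-autosomal
SEX_CHROMS = {"X", "Y", "XY", "MT", "M"}


@dataclass(frozen=True)
class QcThresholds:
    sample_call_rate_min: float = 0.96
    maf_min: float = 0.05
    hwe_p_max: float = 0.001
    snp_missing_max: float = 0.05
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "maf_min", "hwe_p_max", "snp_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Counts of samples/SNPs removed at each QC stage, in filter order."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    snps_removed_missing: int = 0
    snps_removed_nonautosomal: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    removed_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_call_rate", self.samples_removed_call_rate),
            ("snps_in", self.n_snps_in),
            ("snps_removed_maf", self.snps_removed_maf),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_removed_missing", self.snps_removed_missing),
            ("snps_removed_nonautosomal", self.snps_removed_nonautosomal),
            ("samples_out", self.n_samples_out),
            ("snps_out", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and enumerates the exact
    distribution of the heterozygote count (Wigginton, Cutler & Abecasis
    2005); the returned P-value is the summed probability of all heterozygote
    configurations no more probable than the observed one.

    Parameters are genotype counts for an arbitrary biallelic SNP; the
    P-value is in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples (all missing)")
    # rare-allele copy count; heterozygote count shares its parity
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # enumerate P(het = h | allele counts) over h with h ≡ n_rare (mod 2)
    h_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities from the conditional hypergeometric-type
    # distribution: P(h) ∝ 2^h * n! / (h! * n_hom_rare! * n_hom_common!)
    from scipy.special import gammaln

    hom_rare = (n_rare - h_values) // 2
    hom_common = n - h_values - hom_rare
    logp = (
        h_values * np.log(2.0)
        - gammaln(h_values + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[h_values == n_Aa][0]
    # numerical tolerance so ties (equal probability) count as "as extreme"
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        n_aa = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        out[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return out


def apply_qc(geno: GenotypeMatrix, thr: QcThresholds | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Run the fixed-order QC cascade and return filtered genotypes + report.

    Order: sample call rate → SNP MAF → HWE exact test → SNP missingness →
    autosome restriction.  Thresholds are exclusive: a value exactly at the
    threshold survives (e.g. call rate 0.96, MAF 0.05).  HWE removes SNPs
    with exact P <= ``hwe_p_max``.  Raises if no SNP survives.
    """
    thr = thr or QcThresholds()
    report = QcReport(n_samples_in=geno.n_samples, n_snps_in=geno.n_snps)

    x = geno.dosages
    # 1. samples by call rate
    call_rate = 1.0 - x.isna().mean(axis=1)
    keep_samples = call_rate >= thr.sample_call_rate_min
    report.samples_removed_call_rate = int((~keep_samples).sum())
    report.removed_samples = list(x.index[~keep_samples])
    x = x.loc[keep_samples]

    # 2. SNPs by MAF
    freq = x.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= thr.maf_min
    keep &= ~freq.isna()
    report.snps_removed_maf = int((~keep).sum())
    x = x.loc[:, keep]

    # 3. HWE exact test
    hwe_p = _hwe_pvalues(x.to_numpy(dtype=float))
    keep_hwe = hwe_p > thr.hwe_p_max
    report.snps_removed_hwe = int((~keep_hwe).sum())
    x = x.loc[:, keep_hwe]

    # 4. SNP missingness
    miss = x.isna().mean(axis=0)
    keep_miss = miss <= thr.snp_missing_max
    report.snps_removed_missing = int((~keep_miss).sum())
    x = x.loc[:, keep_miss]

    # 5. autosome restriction (sex chromosomes and unmapped scaffolds out)
    snp_map = geno.snp_map.set_index("snp_id").loc[list(x.columns)].reset_index()
    if thr.autosomes_only:
        chrom = snp_map["chrom"].astype(str).str.upper()
        is_autosome = ~chrom.isin(SEX_CHROMS) & ~chrom.str.startswith("SCAFFOLD") & (chrom != "0")
        report.snps_removed_nonautosomal = int((~is_autosome).sum())
        snp_map = snp_map.loc[list(is_autosome)].reset_index(drop=True)
        x = x.loc[:, list(snp_map["snp_id"])]

    if x.shape[1] == 0:
        raise ValueError("no SNPs survive QC")
    report.n_samples_out = x.shape[0]
    report.n_snps_out = x.shape[1]
    return GenotypeMatrix(x, snp_map), report


def ld_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared dosage correlation (composite LD) between two SNPs.

    Missing entries are dropped pairwise; at least two complete pairs and
    polymorphism in both vectors are required.
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic SNP: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
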