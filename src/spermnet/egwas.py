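"""Expression GWAS: per-gene association of abundance on SNP dosage, plus
the double filter tying expression QTL to phenotype-relevant SNPs and genes.

The association model is intentionally minimal (the RNA-seq subset is
small):

    Y = mu + SNP + e

a simple linear regression of log2 abundance on dosage, one (SNP, gene)
pair at a time, with Benjamini-Hochberg FDR within each gene's scan
(``fdr_scope="per_gene"``, the default) or pooled over all pairs.

Retained eQTL must then pass two conditions: (i) the SNP is itself an
FDR-significant hit in the phenotype GWAS, and (ii) the gene's abundance
is significantly correlated with the same phenotype as that GWAS hit.
Records passing both are annotated with the linking trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, GenotypeMatrix
from .expression import pearson_p
from .gwas import bh_fdr

__all__ = ["egwas_scan", "filter_egwas"]


def egwas_scan(
    geno: GenotypeMatrix,
    abundances: AbundanceMatrix,
    annotation: pd.DataFrame | None = None,
    *,
    cis_window_bp: int = 1_000_000,
    fdr_scope: str = "per_gene",
) -> pd.DataFrame:
    """Regress every gene's abundance on every SNP dosage.

    Returns a long DataFrame (snp_id, gene_id, beta, p, q, cis_trans).
    Samples are intersected between genotypes and abundances; fewer than 3
    shared samples is an error.  A pair is *cis* when SNP and gene sit on
    the same chromosome within ``cis_window_bp`` of the gene body
    (requires ``annotation``); everything else, including unannotated
    genes, is *trans*.
    """
    if fdr_scope not in ("per_gene", "pooled"):
        raise ValueError("fdr_scope must be 'per_gene' or 'pooled'")
    samples = [s for s in geno.sample_ids if s in abundances.sample_ids]
    if len(samples) < 3:
        raise ValueError("fewer than 3 samples shared by genotypes and RNA-seq")
    sub = geno.subset_samples(samples)
    dos = sub.mean_imputed()                       # n x m
    expr = abundances.values[samples].to_numpy()   # g x n
    n, m = dos.shape

    # per-(SNP, gene) simple regression via correlations
    dc = dos - dos.mean(axis=0, keepdims=True)
    ec = expr - expr.mean(axis=1, keepdims=True)
    d_sd = dc.std(axis=0)
    e_sd = ec.std(axis=1)
    mono = d_sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (ec @ dc) / (n * np.outer(e_sd, np.where(mono, np.nan, d_sd)))
        beta = R * np.outer(e_sd, 1.0 / np.where(mono, np.nan, d_sd))
    P = pearson_p(np.nan_to_num(R), n)
    P[:, mono] = 1.0
    beta = np.nan_to_num(beta)

    if fdr_scope == "per_gene":
        Q = np.vstack([bh_fdr(P[gi]) for gi in range(P.shape[0])])
    else:
        Q = bh_fdr(P.ravel()).reshape(P.shape)

    gene_ids = abundances.feature_ids
    snp_ids = sub.snp_ids
    out = pd.DataFrame(
        {
            "snp_id": np.tile(snp_ids, len(gene_ids)),
            "gene_id": np.repeat(gene_ids, len(snp_ids)),
            "beta": beta.ravel(),
            "p": P.ravel(),
            "q": Q.ravel(),
        }
    )

    out["cis_trans"] = "trans"
    if annotation is not None:
        ann = annotation.set_index("gene_id")
        smap = sub.snp_map.set_index("snp_id")
        chrom = out["snp_id"].map(smap["chrom"]).astype(str)
        bp = out["snp_id"].map(smap["bp"])
        g_chrom = out["gene_id"].map(ann["chrom"]).astype(str)
        g_start = out["gene_id"].map(ann["start"])
        g_end = out["gene_id"].map(ann["end"])
        dist = np.maximum(g_start - bp, 0) + np.maximum(bp - g_end, 0)
        is_cis = (chrom == g_chrom) & (dist <= cis_window_bp) & g_start.notna()
        out.loc[is_cis.fillna(False), "cis_trans"] = "cis"
    return out


def filter_egwas(
    eqtl: pd.DataFrame,
    gwas_hits: pd.DataFrame,
    trait_correlations: pd.DataFrame,
    *,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Keep eQTL whose SNP is a GWAS hit and whose gene correlates with the
    same trait.

    ``gwas_hits`` needs columns snp_id, trait (FDR-significant phenotype
    associations); ``trait_correlations`` is the output of the expression
    screen (feature_id, trait, significant).  Output adds ``linked_trait``
    (comma-joined when several traits link the pair).
    """
    sig = eqtl[eqtl["q"] <= fdr_threshold]
    if sig.empty:
        return sig.assign(linked_trait=pd.Series(dtype=object))

    snp_traits = gwas_hits.groupby("snp_id")["trait"].agg(set).to_dict()
    gene_traits = (
        trait_correlations[trait_correlations["significant"]]
        .groupby("feature_id")["trait"]
        .agg(set)
        .to_dict()
    )
    keep_rows = []
    linked = []
    for _, row in sig.iterrows():
        common = snp_traits.get(row["snp_id"], set()) & gene_traits.get(
            row["gene_id"], set()
        )
        if common:
            keep_rows.append(row)
            linked.append(",".join(sorted(common)))
    if not keep_rows:
        return sig.iloc[0:0].assign(linked_trait=pd.Series(dtype=object))
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    out["linked_trait"] = linked
    return out
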