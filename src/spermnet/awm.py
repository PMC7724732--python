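"""Associated weight matrix (AWM) construction from a multi-trait scan.

The AWM is a genes x traits matrix of standardized SNP additive effects
built around a *key phenotype* (here the percentage of viable spermatozoa
at 5 min, VIAB_5, since membrane-intact cells are a precondition for
fertilization).  SNP selection proceeds in four stages:

1. SNPs associated with the key trait at P <= 0.01;
2. plus SNPs associated (P <= 0.01) with at least max(2, ceil(Ap))
   non-key traits, where Ap is the average number of non-key traits
   associated per stage-1 SNP (the data-driven dependency threshold,
   floored at 2);
3. keep SNPs lying either within 2500 bp of the nearest annotated gene or
   more than 1 Mbp from any gene, assigning each kept SNP to its nearest
   gene (SNPs with no gene on their chromosome carry no assignment and
   drop out at stage 4);
4. per gene, retain the single SNP with the smallest key-trait P-value.

Each selected gene contributes one row filled with its SNP's additive
effect for every trait (significant or not), z-standardized within trait
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AWMatrix", "select_awm_snps", "build_awm"]


@dataclass
class AWMatrix:
    """Genes x traits matrix of column-standardized SNP effects."""

    matrix: pd.DataFrame          # index: gene_id; columns: traits
    row_meta: pd.DataFrame        # gene_id, snp_id, chrom, bp, key_p
    key_trait: str
    ap: float                     # realized dependency threshold

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise AssertionError("duplicate gene rows in AWM")


def _stack_scans(scans: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide per-SNP beta and p matrices (SNPs x traits) from per-trait scans."""
    betas = {}
    ps = {}
    for trait, scan in scans.items():
        s = scan.set_index("snp_id")
        betas[trait] = s["beta"]
        ps[trait] = s["p"]
    return pd.DataFrame(betas), pd.DataFrame(ps)


def _distance_to_gene(bp: int, start: int, end: int) -> int:
    if bp < start:
        return start - bp
    if bp > end:
        return bp - end
    return 0


def select_awm_snps(
    scans: dict[str, pd.DataFrame],
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    key_trait: str = "VIAB_5",
    p_threshold: float = 0.01,
    near_bp: int = 2500,
    far_bp: int = 1_000_000,
    selection: str = "union",
) -> pd.DataFrame:
    """Run the four-stage AWM SNP selection.

    Returns a DataFrame (snp_id, gene_id, chrom, bp, key_p, stage) with one
    row per selected SNP (one per gene).  ``selection="union"`` (default)
    takes key-trait SNPs plus Ap-qualifying SNPs; ``"sequential"`` requires
    stage-2 candidates to come from the stage-1 set.
    """
    if key_trait not in scans:
        raise ValueError(f"key trait {key_trait!r} missing from scans")
    if selection not in ("union", "sequential"):
        raise ValueError("selection must be 'union' or 'sequential'")
    betas, ps = _stack_scans(scans)
    non_key = [t for t in ps.columns if t != key_trait]

    stage1 = ps.index[ps[key_trait] <= p_threshold]
    if len(stage1) == 0:
        raise ValueError(
            f"no SNPs associated with {key_trait} at P <= {p_threshold}; "
            "consider a looser threshold"
        )

    # Ap: mean number of associated non-key traits over stage-1 SNPs
    nk_counts = (ps[non_key] <= p_threshold).sum(axis=1)
    ap = float(nk_counts.loc[stage1].mean())
    ap_floor = max(2, int(np.ceil(ap)))

    if selection == "union":
        stage2 = ps.index[nk_counts >= ap_floor]
        selected = stage1.union(stage2)
    else:
        stage2 = stage1[nk_counts.loc[stage1] >= ap_floor]
        selected = stage1.union(stage2)

    # stage 3: distance to nearest annotated gene
    smap = snp_map.set_index("snp_id")
    ann_by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in annotation.groupby(annotation["chrom"].astype(str))
    }
    rows = []
    n_no_gene = 0
    for snp in selected:
        if snp not in smap.index:
            continue
        chrom = str(smap.loc[snp, "chrom"])
        bp = int(smap.loc[snp, "bp"])
        genes = ann_by_chrom.get(chrom)
        if genes is None or genes.empty:
            n_no_gene += 1   # d = inf > 1 Mbp: passes the rule, but no gene
            continue
        d = genes.apply(
            lambda g: _distance_to_gene(bp, int(g["start"]), int(g["end"])), axis=1
        )
        i_min = d.idxmin()
        d_min = int(d.loc[i_min])
        # keep only near-gene (d < 2500 bp) or gene-desert (d > 1 Mbp) SNPs;
        # either way the SNP is assigned to its nearest gene
        if d_min < near_bp or d_min > far_bp:
            rows.append(
                {
                    "snp_id": snp,
                    "gene_id": genes.loc[i_min, "gene_id"],
                    "chrom": chrom,
                    "bp": bp,
                    "key_p": float(ps.loc[snp, key_trait]),
                }
            )
    if n_no_gene:
        warnings.warn(
            f"{n_no_gene} selected SNPs had no assignable gene and were dropped"
        )
    if not rows:
        raise ValueError("no SNPs survive the gene-distance rule")
    cand = pd.DataFrame(rows)

    # stage 4: min key-trait p per gene (ties -> smallest snp_id)
    cand = cand.sort_values(["gene_id", "key_p", "snp_id"], kind="mergesort")
    picked = cand.groupby("gene_id", sort=True).first().reset_index()
    picked.attrs["ap"] = ap
    return picked


def build_awm(
    selected: pd.DataFrame,
    scans: dict[str, pd.DataFrame],
    *,
    key_trait: str = "VIAB_5",
) -> AWMatrix:
    """Fill the AWM with signed betas and z-score each trait column.

    ``selected`` is the output of :func:`select_awm_snps`.
    """
    betas, _ = _stack_scans(scans)
    mat = betas.loc[selected["snp_id"]].copy()
    mat.index = selected["gene_id"].tolist()
    mat = mat.sort_index()
    meta = selected.set_index("gene_id").loc[mat.index].reset_index()

    std = mat.std(axis=0, ddof=0)
    if (std == 0).any():
        zero_cols = list(std.index[std == 0])
        warnings.warn(f"constant AWM columns left uncentered-scaled: {zero_cols}")
        std = std.replace(0, 1.0)
    z = (mat - mat.mean(axis=0)) / std
    ap = float(selected.attrs.get("ap", np.nan))
    return AWMatrix(matrix=z, row_meta=meta, key_trait=key_trait, ap=ap)
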