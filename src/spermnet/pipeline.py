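"""End-to-end orchestration of the synthetic study.

``run_pipeline`` chains every stage — genotype simulation, QC, GRM, the
25-trait mixed-model GWAS, abundance filtering and correlation screens,
the expression GWAS double filter, AWM construction, PCIT networks,
network intersection/augmentation and the prediction layer — and returns
all intermediate artifacts in one result object.  ``write_outputs`` dumps
the externally visible tables deterministically (fixed row order and float
formatting), so two runs with the same configuration produce byte-
identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .awm import AWMatrix, build_awm, select_awm_snps
from .datatypes import AbundanceMatrix, GenotypeMatrix, Network
from .egwas import egwas_scan, filter_egwas
from .expression import (
    ExprVarComponents,
    correlate_traits,
    expr_variance_components,
    filter_abundances,
)
from .gwas import QtlInterval, adjust_phenotypes, run_gwas
from .networks import (
    annotate_nodes,
    build_final_network,
    build_rna_network,
    build_snp_network,
    intersect_networks,
    network_summary,
)
from .pcit import mirna_gene_edges
from .prediction import (
    RnaModel,
    SnpPanel,
    all_subsets_r2,
    build_snp_panel,
    candidate_gene_pool,
    panel_variance_explained,
    select_common_genes,
    stepwise_fit,
)
from .qc import QcReport, QcThresholds, apply_qc
from .relatedness import GRM, compute_grm
from .sim import SimConfig, simulate_abundances, simulate_annotation, simulate_genotypes, simulate_phenotypes

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineResult:
    config: SimConfig
    genotypes: GenotypeMatrix
    qc_report: QcReport
    traits: pd.DataFrame
    adjusted_traits: pd.DataFrame
    annotation: pd.DataFrame
    grm: GRM
    scans: dict[str, pd.DataFrame]
    intervals: list[QtlInterval]
    genes_raw: AbundanceMatrix
    genes: AbundanceMatrix
    mirnas: AbundanceMatrix
    gene_correlations: pd.DataFrame
    mirna_correlations: pd.DataFrame
    expr_varcomp: ExprVarComponents
    eqtl_all: pd.DataFrame
    eqtl_filtered: pd.DataFrame
    awm: AWMatrix
    snp_network: Network
    rna_network: Network
    shared_network: Network
    final_network: Network
    mirna_edges: pd.DataFrame
    gene_pool: list[str]
    common_genes: list[str]
    rna_models: dict[str, RnaModel]
    panel: SnpPanel
    panel_variance: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        return network_summary(
            {
                "snp": self.snp_network,
                "rna": self.rna_network,
                "shared": self.shared_network,
                "final": self.final_network,
            }
        )


def run_pipeline(
    cfg: SimConfig | None = None,
    *,
    key_trait: str = "VIAB_5",
    pool_size: int = 10,
    model_genes: int = 10,
    egwas_max_snps: int | None = None,
) -> PipelineResult:
    """Run the whole analysis on freshly simulated data.

    ``pool_size`` caps the all-subsets candidate pool (2^p fits per
    trait); ``egwas_max_snps`` optionally restricts the expression scan to
    the first so-many SNPs (the scan is the single biggest matrix).
    """
    cfg = cfg or SimConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        geno_raw = simulate_genotypes(cfg)
        traits = simulate_phenotypes(geno_raw, cfg)
        genes_raw, mirnas_raw = simulate_abundances(cfg, traits)
        annotation = simulate_annotation(cfg)

        geno, qc_report = apply_qc(geno_raw, QcThresholds())
        traits = traits.loc[geno.sample_ids]
        grm = compute_grm(geno)

        scans, intervals = run_gwas(geno, traits, grm)
        adjusted = adjust_phenotypes(traits)

        genes = filter_abundances(genes_raw)
        mirnas = filter_abundances(mirnas_raw)
        gene_corr = correlate_traits(genes, adjusted)
        mirna_corr = correlate_traits(mirnas, adjusted)

        # external-effects variance model on a gene subsample (the MME
        # solver is O(q^3)); reported only — abundances stay uncorrected
        rna_cov = traits.loc[[s for s in genes.sample_ids if s in traits.index],
                             ["farm", "season_year", "age"]]
        sub_ids = genes.feature_ids[: min(60, genes.n_features)]
        expr_vc = expr_variance_components(
            AbundanceMatrix(genes.values.loc[sub_ids], kind="mRNA", log2=True),
            rna_cov,
        )

        hits = _significant_hits(scans)
        e_geno = geno
        if egwas_max_snps is not None and egwas_max_snps < geno.n_snps:
            e_geno = geno.subset_snps(geno.snp_ids[:egwas_max_snps])
        eqtl_all = egwas_scan(e_geno, genes, annotation)
        eqtl_filtered = filter_egwas(eqtl_all, hits, gene_corr)

        selected = select_awm_snps(
            scans, geno.snp_map, annotation, key_trait=key_trait
        )
        awm = build_awm(selected, scans, key_trait=key_trait)

        snp_net = build_snp_network(awm)
        rna_net = build_rna_network(genes)
        shared = intersect_networks(snp_net, rna_net)
        mir_edges = mirna_gene_edges(mirnas, genes)
        final = build_final_network(
            shared, rna_net, gene_corr, mir_edges, annotation
        )
        annotate_nodes(snp_net, gene_corr, annotation, shared_nodes=set(shared.nodes))
        annotate_nodes(rna_net, gene_corr, annotation, shared_nodes=set(shared.nodes))

        pool = candidate_gene_pool(
            final, gene_corr, genes_raw, max_genes=pool_size
        )
        pool_values = genes_raw.values.loc[pool]
        trait_cols = [c for c in adjusted.columns if c not in ("farm", "season_year", "age")]
        subset_tables = {
            t: all_subsets_r2(pool_values, traits[t]) for t in trait_cols
        }
        common = select_common_genes(subset_tables, k=model_genes)
        rna_models = {
            t: stepwise_fit(genes_raw.values.loc[common], traits[t], t)
            for t in trait_cols
        }

        panel = build_snp_panel(
            intervals, eqtl_filtered, shared, gene_corr, scans, geno.snp_map, annotation
        )
        panel_var = panel_variance_explained(panel, geno, traits)

    return PipelineResult(
        config=cfg,
        genotypes=geno,
        qc_report=qc_report,
        traits=traits,
        adjusted_traits=adjusted,
        annotation=annotation,
        grm=grm,
        scans=scans,
        intervals=intervals,
        genes_raw=genes_raw,
        genes=genes,
        mirnas=mirnas,
        gene_correlations=gene_corr,
        mirna_correlations=mirna_corr,
        expr_varcomp=expr_vc,
        eqtl_all=eqtl_all,
        eqtl_filtered=eqtl_filtered,
        awm=awm,
        snp_network=snp_net,
        rna_network=rna_net,
        shared_network=shared,
        final_network=final,
        mirna_edges=mir_edges,
        gene_pool=pool,
        common_genes=common,
        rna_models=rna_models,
        panel=panel,
        panel_variance=panel_var,
    )


def _significant_hits(scans: dict[str, pd.DataFrame], threshold: float = 0.05) -> pd.DataFrame:
    rows = []
    for trait, scan in scans.items():
        hit = scan[scan["q"] <= threshold].copy()
        if not hit.empty:
            hit["trait"] = trait
            rows.append(hit)
    if not rows:
        return pd.DataFrame(columns=["snp_id", "chrom", "bp", "p", "q", "trait"])
    return pd.concat(rows, ignore_index=True)


def write_outputs(result: PipelineResult, outdir) -> list[Path]:
    """Write every externally visible artifact; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    io_formats.write_plink_text(
        result.genotypes, _w(out / "genotypes.ped"), _w(out / "genotypes.map")
    )
    io_formats.write_trait_table(result.traits, _w(out / "traits.tsv"))
    io_formats.write_abundance_tsv(result.genes, _w(out / "genes_log2.tsv"))
    io_formats.write_abundance_tsv(result.mirnas, _w(out / "mirnas_log2.tsv"))
    io_formats.write_annotation_tsv(result.annotation, _w(out / "annotation.tsv"))
    result.qc_report.to_frame().to_csv(_w(out / "qc_report.tsv"), sep="\t", index=False)

    scan_rows = []
    for trait in sorted(result.scans):
        s = result.scans[trait].copy()
        s.insert(0, "trait", trait)
        scan_rows.append(s)
    pd.concat(scan_rows, ignore_index=True).to_csv(
        _w(out / "gwas_scans.tsv"), sep="\t", index=False, float_format="%.8g"
    )

    iv_rows = [
        {
            "trait": iv.trait,
            "chrom": iv.chrom,
            "start_bp": iv.start_bp,
            "end_bp": iv.end_bp,
            "n_snps": len(iv.snp_ids),
            "lead_snp": iv.lead_snp,
            "singleton": iv.singleton,
        }
        for iv in result.intervals
    ]
    pd.DataFrame(iv_rows).to_csv(_w(out / "gwas_intervals.tsv"), sep="\t", index=False)

    pd.DataFrame(
        sorted(result.expr_varcomp.shares.items()), columns=["component", "share"]
    ).to_csv(_w(out / "expression_variance_shares.tsv"), sep="\t", index=False,
             float_format="%.8g")
    result.gene_correlations.to_csv(
        _w(out / "gene_trait_correlations.tsv"), sep="\t", index=False, float_format="%.8g"
    )
    result.mirna_correlations.to_csv(
        _w(out / "mirna_trait_correlations.tsv"), sep="\t", index=False, float_format="%.8g"
    )
    result.eqtl_filtered.to_csv(
        _w(out / "egwas_filtered.tsv"), sep="\t", index=False, float_format="%.8g"
    )
    result.awm.matrix.to_csv(
        _w(out / "awm.tsv"), sep="\t", index_label="gene_id", float_format="%.8g"
    )
    result.awm.row_meta.to_csv(
        _w(out / "awm_rows.tsv"), sep="\t", index=False, float_format="%.8g"
    )

    for name, net in (
        ("snp", result.snp_network),
        ("rna", result.rna_network),
        ("shared", result.shared_network),
        ("final", result.final_network),
    ):
        if net.n_nodes == 0:
            continue
        io_formats.write_network_sif(net, _w(out / f"network_{name}.sif"))
        io_formats.write_network_graphml(net, _w(out / f"network_{name}.graphml"))
        io_formats.write_network_edges(net, _w(out / f"network_{name}_edges.tsv"))
    result.summary_frame().to_csv(_w(out / "network_summary.tsv"), sep="\t", index=False)

    model_rows = [
        {
            "trait": t,
            "r2": m.r2,
            "p_value": m.p_value,
            "n_genes": len(m.coefficients),
            "genes": ",".join(m.selected_genes),
        }
        for t, m in sorted(result.rna_models.items())
    ]
    pd.DataFrame(model_rows).to_csv(
        _w(out / "rna_models.tsv"), sep="\t", index=False, float_format="%.8g"
    )
    result.panel.to_frame(result.genotypes.snp_map).to_csv(
        _w(out / "snp_panel.tsv"), sep="\t", index=False
    )
    result.panel_variance.to_csv(
        _w(out / "panel_variance.tsv"), sep="\t", index=False, float_format="%.8g"
    )
    return written
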