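"""Phenotype-prediction layer: the RNA regression model (all-subsets
screen -> 10 common genes -> per-trait stepwise fit) and the SNP panel
whose GREML variance explained summarizes the pipeline's yield.

The RNA model predicts a semen trait from raw (unadjusted) gene
abundances:

    Y = intercept + sum_j GPE_j + e

where GPE_j is gene j's abundance times its regression coefficient.  Gene
selection runs in three steps: a 20-gene candidate pool from the final
network (trait-correlated, mutually non-adjacent, expressed in every
sample), an exhaustive all-subsets R^2 screen per trait, and a stepwise
(forward entry P <= 0.15, backward stay P <= 0.15, the SAS REG STEPWISE
defaults) fit per trait on the 10 genes most common across traits'
best-per-size subsets.

The SNP panel unions GWAS interval lead SNPs, eGWAS lead SNPs and the
most significant GWAS SNP of each qualifying network gene; its per-trait
phenotypic variance explained comes from GREML with a GRM restricted to
the panel.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, COVARIATE_COLUMNS, GenotypeMatrix, Network
from .expression import significant_trait_counts
from .gwas import QtlInterval
from .relatedness import compute_grm, greml

__all__ = [
    "RnaModel",
    "SnpPanel",
    "candidate_gene_pool",
    "all_subsets_r2",
    "select_common_genes",
    "stepwise_fit",
    "build_snp_panel",
    "panel_variance_explained",
]


@dataclass
class RnaModel:
    trait: str
    intercept: float
    coefficients: dict[str, float]     # gene -> GPE coefficient
    r2: float
    p_value: float                     # overall F-test
    n: int

    @property
    def selected_genes(self) -> list[str]:
        return sorted(self.coefficients)

    def summary(self) -> str:
        lines = [
            f"RNA model for {self.trait}: R^2 = {self.r2:.3f}, P = {self.p_value:.3g}",
            f"  intercept: {self.intercept:.4g}",
        ]
        for g, b in sorted(self.coefficients.items()):
            lines.append(f"  {g}: {b:.4g}")
        return "\n".join(lines)


@dataclass
class SnpPanel:
    """De-duplicated SNP set with source tags (gwas_lead | egwas_lead |
    network_gene)."""

    snp_ids: list[str]
    sources: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("panel SNP ids must be unique")
        if not self.snp_ids:
            raise ValueError("empty SNP panel")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "source": [",".join(sorted(self.sources[s])) for s in self.snp_ids],
            }
        )
        if snp_map is not None:
            df = df.merge(snp_map[["snp_id", "chrom", "bp"]], on="snp_id", how="left")
        return df


def candidate_gene_pool(
    final_net: Network,
    trait_correlations: pd.DataFrame,
    abundances: AbundanceMatrix,
    manual_list: list[str] | None = None,
    *,
    min_traits: int = 4,
    max_genes: int = 20,
) -> list[str]:
    """Pick up to 20 mutually non-adjacent, well-correlated, always-
    expressed genes from the final network.

    Filters: (i) significantly correlated with >= ``min_traits`` traits,
    (ii) no final-network edge to an already-picked gene, (iii) abundance
    > 0 in every sample.  ``manual_list`` expresses the external relevance
    ranking: listed genes are considered first, in order; remaining
    eligible genes follow by descending trait count.
    """
    counts = significant_trait_counts(trait_correlations)
    raw = abundances.values
    eligible = []
    for g in final_net.nodes:
        if final_net.nodes[g].get("type") != "gene":
            continue
        if counts.get(g, 0) < min_traits:
            continue
        if g in raw.index and (raw.loc[g] > 0).all():
            eligible.append(g)
    order = sorted(eligible, key=lambda g: (-counts.get(g, 0), g))
    if len(eligible) < 2:
        raise ValueError("fewer than 2 eligible candidate genes")
    if manual_list:
        ranked = [g for g in manual_list if g in eligible]
        ranked += [g for g in order if g not in ranked]
    else:
        ranked = order

    picked: list[str] = []
    for g in ranked:
        if len(picked) >= max_genes:
            break
        if any(final_net.has_edge(g, h) for h in picked):
            continue
        picked.append(g)
    return picked


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return max(0.0, 1.0 - float((resid**2).sum()) / tss)


def all_subsets_r2(
    pool_abundances: pd.DataFrame,
    trait: pd.Series,
) -> pd.DataFrame:
    """OLS R^2 of every nonempty gene subset for one trait.

    ``pool_abundances`` is genes x samples (raw values); refuses pools
    above 20 genes (2^20 fits).  Returns a DataFrame (subset, size, r2)
    with subsets as sorted gene-id tuples.
    """
    genes = list(pool_abundances.index)
    p = len(genes)
    if p > 20:
        raise ValueError(f"pool of {p} genes exceeds the 20-gene all-subsets guard")
    samples = [s for s in pool_abundances.columns if s in trait.index]
    X_all = pool_abundances[samples].to_numpy().T
    y = trait.loc[samples].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    X_all, y = X_all[ok], y[ok]

    rows = []
    for size in range(1, p + 1):
        for combo in itertools.combinations(range(p), size):
            r2 = _ols_r2(X_all[:, combo], y)
            rows.append((tuple(genes[i] for i in combo), size, r2))
    return pd.DataFrame(rows, columns=["subset", "size", "r2"])


def select_common_genes(
    subset_tables: dict[str, pd.DataFrame], k: int = 10
) -> list[str]:
    """Genes most common across traits' best-per-size subsets.

    For each trait and model size, the best-R^2 subset wins (ties break to
    the lexicographically smallest tuple); gene occurrences are tallied
    over all winners and the ``k`` most frequent genes returned (ties
    lexicographic).
    """
    tally: dict[str, int] = {}
    pool: set[str] = set()
    for table in subset_tables.values():
        pool.update(g for s in table["subset"] for g in s)
        best = table.sort_values(
            ["size", "r2", "subset"], ascending=[True, False, True], kind="mergesort"
        ).groupby("size").first()
        for subset in best["subset"]:
            for g in subset:
                tally[g] = tally.get(g, 0) + 1
    if k >= len(pool):
        if k > len(pool):
            warnings.warn(f"k={k} exceeds pool size {len(pool)}; returning whole pool")
        return sorted(pool)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:k]]


def _fit_ols(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (beta, se, t_pvalues, r2, overall_F_p)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the model size")
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * s2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    k = p - 1
    if k > 0 and r2 < 1.0 and tss > 0:
        F = (r2 / k) / ((1.0 - r2) / df)
        f_p = float(stats.f.sf(F, k, df))
    else:
        f_p = 1.0 if k == 0 else 0.0
    return beta, se, pvals, max(r2, 0.0), f_p


def stepwise_fit(
    pool_abundances: pd.DataFrame,
    trait: pd.Series,
    trait_name: str | None = None,
    *,
    p_enter: float = 0.15,
    p_stay: float = 0.15,
) -> RnaModel:
    """Forward-backward stepwise OLS on the selected gene pool.

    Entry: the candidate with the smallest partial P enters while that P
    is <= ``p_enter``; after every entry, included genes with partial
    P > ``p_stay`` leave.  With no entering predictor the intercept-only
    model (R^2 = 0) is returned.
    """
    genes = list(pool_abundances.index)
    samples = [s for s in pool_abundances.columns if s in trait.index]
    y = trait.loc[samples].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    X_pool = pool_abundances[samples].to_numpy().T[ok]
    n = len(y)
    name = trait_name or str(trait.name)
    if np.var(y) == 0.0:
        return RnaModel(name, float(y.mean()), {}, 0.0, 1.0, n)

    included: list[int] = []
    while True:
        changed = False
        # forward step
        best_j, best_p = None, np.inf
        for j in range(len(genes)):
            if j in included:
                continue
            cols = included + [j]
            X = np.column_stack([np.ones(n), X_pool[:, cols]])
            if X.shape[1] >= n:
                continue
            _, _, pvals, _, _ = _fit_ols(X, y)
            if pvals[-1] < best_p:
                best_j, best_p = j, pvals[-1]
        if best_j is not None and best_p <= p_enter:
            included.append(best_j)
            changed = True
        # backward step
        while included:
            X = np.column_stack([np.ones(n), X_pool[:, included]])
            _, _, pvals, _, _ = _fit_ols(X, y)
            worst = int(np.argmax(pvals[1:]))
            if pvals[1 + worst] > p_stay:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        return RnaModel(name, float(y.mean()), {}, 0.0, 1.0, n)
    X = np.column_stack([np.ones(n), X_pool[:, included]])
    beta, _, _, r2, f_p = _fit_ols(X, y)
    coefs = {genes[j]: float(b) for j, b in zip(included, beta[1:])}
    return RnaModel(name, float(beta[0]), coefs, float(r2), float(f_p), n)


def build_snp_panel(
    intervals: list[QtlInterval],
    egwas_records: pd.DataFrame,
    shared_net: Network,
    trait_correlations: pd.DataFrame,
    scans: dict[str, pd.DataFrame],
    snp_map: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    min_traits: int = 4,
    gene_window_bp: int = 2500,
) -> SnpPanel:
    """Union of GWAS interval leads, eGWAS leads and per-network-gene
    top GWAS SNPs, de-duplicated with source tags; autosomal only.

    Network genes qualify when in the shared network and significantly
    correlated with >= ``min_traits`` traits; each contributes the SNP
    with the smallest GWAS P (over all traits) within the gene body
    extended by ``gene_window_bp``.  Singleton GWAS intervals contribute
    no lead.
    """
    from .gwas import _is_placed

    sources: dict[str, set[str]] = {}

    def add(snp: str, tag: str) -> None:
        sources.setdefault(snp, set()).add(tag)

    for iv in intervals:
        if not iv.singleton:
            add(iv.lead_snp, "gwas_lead")

    if not egwas_records.empty:
        leads = (
            egwas_records.sort_values(["gene_id", "p", "snp_id"], kind="mergesort")
            .groupby("gene_id")
            .first()["snp_id"]
        )
        for snp in leads:
            add(str(snp), "egwas_lead")

    counts = significant_trait_counts(trait_correlations)
    qualifying = [
        g for g in shared_net.nodes if counts.get(g, 0) >= min_traits
    ]
    if qualifying:
        min_p = None
        for trait, scan in scans.items():
            s = scan.set_index("snp_id")["p"]
            min_p = s if min_p is None else np.minimum(min_p, s)
        smap = snp_map.set_index("snp_id")
        ann = annotation.set_index("gene_id")
        for g in sorted(qualifying):
            if g not in ann.index:
                continue
            chrom = str(ann.loc[g, "chrom"])
            lo = int(ann.loc[g, "start"]) - gene_window_bp
            hi = int(ann.loc[g, "end"]) + gene_window_bp
            in_gene = smap[
                (smap["chrom"].astype(str) == chrom)
                & (smap["bp"] >= lo)
                & (smap["bp"] <= hi)
            ]
            if in_gene.empty:
                continue
            cand = min_p.loc[in_gene.index]
            add(str(cand.idxmin()), "network_gene")

    # autosomal restriction
    smap = snp_map.set_index("snp_id")
    snps = [
        s
        for s in sorted(sources)
        if s in smap.index and _is_placed(str(smap.loc[s, "chrom"]))
        and str(smap.loc[s, "chrom"]).upper() not in {"X", "Y", "XY", "MT"}
    ]
    return SnpPanel(snp_ids=snps, sources={s: sources[s] for s in snps})


def panel_variance_explained(
    panel: SnpPanel,
    geno: GenotypeMatrix,
    traits: pd.DataFrame,
    *,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """GREML variance explained per trait with the panel-restricted GRM.

    Returns a DataFrame (trait, var_explained, se, converged); samples
    with a missing phenotype are dropped listwise per trait.
    """
    missing = [s for s in panel.snp_ids if s not in geno.snp_ids]
    if missing:
        raise ValueError(f"panel SNPs absent from genotypes: {missing[:5]}")
    sub = geno.subset_snps(panel.snp_ids)
    grm = compute_grm(sub)

    cov_cols = [c for c in COVARIATE_COLUMNS if c in traits.columns]
    if trait_names is None:
        trait_names = [c for c in traits.columns if c not in cov_cols]
    from .gwas import _covariate_design

    rows = []
    for name in trait_names:
        y = traits[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        X = (
            _covariate_design(traits.loc[ok, cov_cols])
            if cov_cols
            else np.ones((int(ok.sum()), 1))
        )
        gm = grm.matrix.to_numpy()[np.ix_(ok, ok)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = greml(y[ok], X, gm)
        rows.append(
            {
                "trait": name,
                "var_explained": vc.h2,
                "se": vc.se_h2,
                "converged": vc.converged,
            }
        )
    return pd.DataFrame(rows)
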