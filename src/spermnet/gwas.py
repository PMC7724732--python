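"""Phenotype adjustment, mixed-linear-model association, FDR and QTL
intervals.

The association model per SNP is

    y = mu + delta*SNP + Farm + SeasonYear + Age + u + e,   u ~ N(0, G su2)

fit in the P3D/EMMAX fashion: the variance components (su2, se2) are
estimated once by GREML under the no-SNP null, then every SNP is tested by
a generalized-least-squares Wald test with that covariance held fixed.  SNP
dosages enter centered (-1, 0, 1 coding); betas are per-allele additive
effects.  P-values are corrected per trait with Benjamini-Hochberg FDR and
significant SNPs are chained into QTL intervals: consecutive hits on a
chromosome belong to one interval while gaps stay below 5 Mbp; a gap of
exactly 5 Mbp or more starts a new interval.  Intervals containing a single
SNP are kept in the output but flagged as singletons (downstream candidate
steps skip them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import COVARIATE_COLUMNS, GenotypeMatrix
from .relatedness import GRM, VARIANCE_FLOOR, greml

__all__ = [
    "adjust_phenotypes",
    "mlm_assoc",
    "bh_fdr",
    "cluster_intervals",
    "run_gwas",
    "QtlInterval",
]

INTERVAL_GAP_BP = 5_000_000


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + treatment-coded dummies for the categorical covariates."""
    parts = [np.ones((len(covariates), 1))]
    for col in covariates.columns:
        d = pd.get_dummies(covariates[col].astype(str), drop_first=True)
        if d.shape[1]:
            parts.append(d.to_numpy(dtype=float))
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design (aliased factor levels)")
    return X


def adjust_phenotypes(traits: pd.DataFrame) -> pd.DataFrame:
    """Residualize every trait on the farm/season-year/age fixed effects.

    Ratio traits (90/5 incubation) are computed from the raw values before
    adjustment when absent.  Covariate columns are carried through
    unchanged; trait columns become OLS residuals.
    """
    from .sim import RATIO_TRAITS

    traits = traits.copy()
    for rname, (num, den) in RATIO_TRAITS.items():
        if rname not in traits.columns and num in traits.columns and den in traits.columns:
            traits[rname] = traits[num] / traits[den].replace(0, np.nan)

    cov_cols = [c for c in COVARIATE_COLUMNS if c in traits.columns]
    trait_cols = [c for c in traits.columns if c not in cov_cols]
    if not cov_cols:
        out = traits[trait_cols] - traits[trait_cols].mean()
        return out
    X = _covariate_design(traits[cov_cols])
    out = traits.copy()
    for c in trait_cols:
        y = traits[c].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - X[ok] @ beta
        out[c] = resid
    return out


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mlm_assoc(
    geno: GenotypeMatrix,
    trait: pd.Series,
    covariates: pd.DataFrame,
    G: GRM,
    *,
    exact_per_snp: bool = False,
) -> pd.DataFrame:
    """Single-SNP mixed-model scan for one trait.

    Returns a DataFrame (snp_id, chrom, bp, beta, se, p, q, maf) in map
    order.  ``exact_per_snp=True`` refits the variance components for every
    SNP instead of reusing the null-model fit (slow; P3D is the default).
    Traits whose null fit puts su2 at the boundary fall back to ordinary
    least squares with a warning (the two are equivalent there).
    """
    y = trait.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    if not ok.all():
        geno = geno.subset_samples(np.array(geno.sample_ids)[ok])
        covariates = covariates.loc[ok]
        gm = G.matrix.loc[list(geno.sample_ids), list(geno.sample_ids)]
        G = GRM(gm, G.n_snps_used)
        y = y[ok]
    X = _covariate_design(covariates)
    n, p_fixed = X.shape

    null = greml(y, X, G)
    boundary = null.sigma_u2 <= 10 * VARIANCE_FLOOR
    if boundary:
        warnings.warn("null-model su2 at boundary; falling back to OLS per SNP")

    g = G.to_numpy()
    d, U = np.linalg.eigh(0.5 * (g + g.T))
    d = np.clip(d, 0.0, None)
    if boundary:
        w = np.ones(n)
        yt, Xt = y, X
        dost = geno.mean_imputed() - 1.0
    else:
        w = 1.0 / (null.sigma_u2 * d + null.sigma_e2)
        yt = U.T @ y
        Xt = U.T @ X
        dost = U.T @ (geno.mean_imputed() - 1.0)

    # GLS-residualize y and dosages against the covariates
    Xw = Xt * w[:, None]
    XtWX_inv = np.linalg.inv(Xt.T @ Xw)
    y_r = yt - Xt @ (XtWX_inv @ (Xw.T @ yt))
    G_r = dost - Xt @ (XtWX_inv @ (Xw.T @ dost))

    num = (G_r * (w[:, None] * y_r[:, None])).sum(axis=0)
    den = (G_r * (w[:, None] * G_r)).sum(axis=0)
    df = n - p_fixed - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        if boundary:
            beta = num / den
            resid_ss = (w * y_r * y_r).sum() - beta * num
            sigma2 = resid_ss / df
            se = np.sqrt(sigma2 / den)
        else:
            beta = num / den
            se = np.sqrt(1.0 / den)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    mono = den <= 1e-12
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    pvals = np.where(mono, 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    if exact_per_snp and not boundary:
        dos = geno.mean_imputed() - 1.0
        for j in range(geno.n_snps):
            if mono[j]:
                continue
            Xj = np.hstack([X, dos[:, [j]]])
            fit = greml(y, Xj, G)
            wj = 1.0 / (fit.sigma_u2 * d + fit.sigma_e2)
            Xjt = U.T @ Xj
            XtWXj = Xjt.T @ (Xjt * wj[:, None])
            bj = np.linalg.solve(XtWXj, (Xjt * wj[:, None]).T @ (U.T @ y))
            cov = np.linalg.inv(XtWXj)
            beta[j] = bj[-1]
            se[j] = np.sqrt(cov[-1, -1])
            pvals[j] = 2.0 * stats.t.sf(abs(beta[j] / se[j]), df)

    freq = geno.allele_freq().to_numpy()
    maf = np.minimum(freq, 1.0 - freq)
    out = geno.snp_map[["snp_id", "chrom", "bp"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pvals
    out["q"] = bh_fdr(pvals)
    out["maf"] = maf
    return out


@dataclass
class QtlInterval:
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    lead_snp: str
    trait: str
    singleton: bool = field(default=False)


def _is_placed(chrom: str) -> bool:
    try:
        int(str(chrom))
        return True
    except ValueError:
        return False


def cluster_intervals(
    hits: pd.DataFrame, *, gap_bp: int = INTERVAL_GAP_BP
) -> list[QtlInterval]:
    """Chain significant SNPs into QTL intervals per trait and chromosome.

    ``hits`` needs columns snp_id, chrom, bp, p, trait.  Consecutive SNPs
    stay in one interval while the gap is strictly below ``gap_bp``
    (default 5 Mbp); a gap of exactly 5 Mbp opens a new interval.  SNPs on
    unplaced scaffolds (non-numeric chromosome labels) are skipped.
    Singleton intervals are returned flagged.
    """
    intervals: list[QtlInterval] = []
    if hits.empty:
        return intervals
    placed = hits[hits["chrom"].astype(str).map(_is_placed)]
    for (trait, chrom), grp in placed.groupby(["trait", "chrom"], sort=True):
        grp = grp.sort_values(["bp", "snp_id"], kind="mergesort")
        current: list[pd.Series] = []
        for _, row in grp.iterrows():
            if current and row["bp"] - current[-1]["bp"] >= gap_bp:
                intervals.append(_make_interval(current, str(trait), str(chrom)))
                current = []
            current.append(row)
        if current:
            intervals.append(_make_interval(current, str(trait), str(chrom)))
    intervals.sort(key=lambda iv: (iv.trait, _chrom_key(iv.chrom), iv.start_bp))
    return intervals


def _chrom_key(c: str):
    try:
        return (0, int(c))
    except ValueError:
        return (1, c)


def _make_interval(rows: list[pd.Series], trait: str, chrom: str) -> QtlInterval:
    lead = min(rows, key=lambda r: (r["p"], r["snp_id"]))
    return QtlInterval(
        chrom=chrom,
        start_bp=int(rows[0]["bp"]),
        end_bp=int(rows[-1]["bp"]),
        snp_ids=[str(r["snp_id"]) for r in rows],
        lead_snp=str(lead["snp_id"]),
        trait=trait,
        singleton=len(rows) == 1,
    )


def manhattan_plot(scan: pd.DataFrame, path, *, fdr_threshold: float = 0.05) -> None:
    """Plain Manhattan plot export (PNG/PDF by extension).

    Chromosomes alternate shading; the red line marks the largest p still
    significant at the FDR threshold (absent when nothing is significant).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    placed = scan[scan["chrom"].astype(str).map(_is_placed)].copy()
    placed["chrom_n"] = placed["chrom"].astype(int)
    placed = placed.sort_values(["chrom_n", "bp"])
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (c, grp) in enumerate(placed.groupby("chrom_n", sort=True)):
        x = grp["bp"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p"]), s=4, color="C0" if i % 2 else "C7")
        ticks.append(offset + grp["bp"].max() / 2)
        labels.append(str(c))
        offset += grp["bp"].max() + 1
    sig = placed[placed["q"] <= fdr_threshold]
    if not sig.empty:
        ax.axhline(-np.log10(sig["p"].max()), color="red", lw=0.8)
    ax.set_xticks(ticks, labels, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_gwas(
    geno: GenotypeMatrix,
    traits: pd.DataFrame,
    G: GRM,
    *,
    trait_names: list[str] | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], list[QtlInterval]]:
    """Scan every trait, collect FDR-significant hits and their intervals.

    Returns (scans, intervals): ``scans`` maps trait name to the per-SNP
    association table; ``intervals`` are QTL intervals over all traits.
    """
    cov_cols = [c for c in COVARIATE_COLUMNS if c in traits.columns]
    if trait_names is None:
        trait_names = [c for c in traits.columns if c not in cov_cols]
    covariates = traits[cov_cols]
    scans: dict[str, pd.DataFrame] = {}
    hit_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in trait_names:
            scan = mlm_assoc(geno, traits[name], covariates, G)
            scans[name] = scan
            hits = scan[scan["q"] <= fdr_threshold].copy()
            if not hits.empty:
                hits["trait"] = name
                hit_rows.append(hits)
    all_hits = (
        pd.concat(hit_rows, ignore_index=True)
        if hit_rows
        else pd.DataFrame(columns=["snp_id", "chrom", "bp", "p", "trait"])
    )
    return scans, cluster_intervals(all_hits)
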