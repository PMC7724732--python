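"""Abundance filtering, the external-effects variance-component model and
trait-abundance correlation screens.

Filtering follows the sperm RNA-seq conventions: genes are kept when their
mean FPKM is at least 10 (discarding low-abundance genes and spurious
mappings), miRNAs when their mean CPM is strictly above 1; surviving values
are stabilized as log2(x + pseudocount).

The variance-component model quantifies how much of the (library x gene)
log2 abundance variation external factors explain:

    Y = mu + Library_i + Gene_j + (Gene x Farm) + (Gene x YearSeason)
         + (Gene x Age) + (Gene x Run) + e

with the library effect fixed and every gene term random.  It is fitted by
EM-REML on Henderson's mixed-model equations.  The gene main effect
dominating the explained variance is the usual justification for leaving
abundances uncorrected downstream, which is also this module's default
stance (it reports, the caller decides).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, sparse

from .datatypes import AbundanceMatrix

__all__ = [
    "filter_abundances",
    "expr_variance_components",
    "correlate_traits",
    "ExprVarComponents",
]


def filter_abundances(
    m: AbundanceMatrix,
    *,
    pseudocount: float = 1.0,
    strict_per_sample: bool = False,
) -> AbundanceMatrix:
    """Apply the abundance screen and log2-stabilize.

    mRNA: mean FPKM >= 10 kept.  miRNA: mean CPM > 1 kept (or CPM > 1 in
    every sample when ``strict_per_sample``).  Raises when nothing
    survives.
    """
    if m.log2:
        raise ValueError("filter expects raw (non-log) abundances")
    vals = m.values
    if m.kind == "mRNA":
        keep = vals.mean(axis=1) >= 10.0
    else:
        if strict_per_sample:
            keep = (vals > 1.0).all(axis=1)
        else:
            keep = vals.mean(axis=1) > 1.0
    kept = vals.loc[keep]
    if kept.empty:
        raise ValueError(f"no {m.kind} features survive the abundance screen")
    return AbundanceMatrix(np.log2(kept + pseudocount), kind=m.kind, log2=True)


@dataclass
class ExprVarComponents:
    """Variance shares of the crossed random-effects abundance model."""

    shares: dict[str, float]  # component name -> share of total variance
    sigma2: dict[str, float]  # raw variance components
    explained: float          # 1 - residual share
    n_iter: int
    converged: bool

    def summary(self) -> str:
        lines = ["Expression variance components (share of total)"]
        for k, v in self.shares.items():
            lines.append(f"  {k:<18s} {v:8.4f}")
        lines.append(f"  explained (non-residual): {self.explained:.4f}")
        return "\n".join(lines)


def expr_variance_components(
    m: AbundanceMatrix,
    covariates: pd.DataFrame,
    *,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ExprVarComponents:
    """EM-REML fit of the crossed gene x external-factor model.

    ``covariates`` is indexed by sample/library id and provides the
    categorical columns ``farm``, ``season_year``, ``age`` and (optionally)
    ``run``.  Factors with fewer than 2 observed levels are dropped with a
    warning.  The response is the long-format log2 abundance (library x
    gene); the library effect is fixed, all gene terms random.
    """
    if not m.log2:
        raise ValueError("variance-component model expects log2 abundances")
    samples = [s for s in m.sample_ids if s in covariates.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 libraries with covariates")
    vals = m.values[samples]
    if float(np.var(vals.to_numpy())) == 0.0:
        raise ValueError("constant response: variance shares undefined")

    n_genes, n_lib = vals.shape
    y = vals.to_numpy().T.ravel()           # library-major long format
    N = y.size
    lib_idx = np.repeat(np.arange(n_lib), n_genes)
    gene_idx = np.tile(np.arange(n_genes), n_lib)

    # fixed design: intercept + library dummies (drop first)
    X = np.zeros((N, n_lib))
    X[:, 0] = 1.0
    for i in range(1, n_lib):
        X[lib_idx == i, i] = 1.0

    factors: dict[str, np.ndarray] = {}
    factor_cols = {"gene_farm": "farm", "gene_year_season": "season_year",
                   "gene_age": "age", "gene_run": "run"}
    for comp, col in factor_cols.items():
        if col not in covariates.columns:
            continue
        codes = np.asarray(
            pd.Categorical(covariates.loc[samples, col].astype(str)).codes, dtype=np.int64
        )
        if len(set(codes)) < 2:
            warnings.warn(f"factor {col!r} has <2 levels; term {comp} dropped")
            continue
        factors[comp] = codes[lib_idx] * n_genes + gene_idx  # gene-within-level

    components: dict[str, np.ndarray] = {"gene": gene_idx}
    components.update(factors)
    q_sizes = {c: int(idx.max()) + 1 for c, idx in components.items()}

    def Z_for(idx: np.ndarray, q: int) -> sparse.csr_matrix:
        return sparse.csr_matrix(
            (np.ones(N), (np.arange(N), idx)), shape=(N, q)
        )

    Zs = {c: Z_for(idx, q_sizes[c]) for c, idx in components.items()}
    Z = sparse.hstack(list(Zs.values()), format="csr")
    q_total = Z.shape[1]
    offsets = np.cumsum([0] + [q_sizes[c] for c in components])

    Xs = sparse.csr_matrix(X)
    XtX = (Xs.T @ Xs).toarray()
    XtZ = (Xs.T @ Z).toarray()
    ZtZ = (Z.T @ Z).toarray()
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    rank_x = np.linalg.matrix_rank(XtX)

    var_y = float(np.var(y, ddof=1))
    sig = {c: var_y / (len(components) + 1) for c in components}
    sig_e = var_y / (len(components) + 1)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = np.concatenate(
            [np.full(q_sizes[c], sig_e / max(sig[c], 1e-10)) for c in components]
        )
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(lam)]])
        rhs = np.concatenate([Xty, Zty])
        Minv = np.linalg.inv(M)
        sol = Minv @ rhs
        u = sol[X.shape[1]:]

        new_sig = {}
        p = X.shape[1]
        for ci, c in enumerate(components):
            sl = slice(p + offsets[ci], p + offsets[ci + 1])
            uc = sol[sl]
            tr_c = np.trace(Minv[sl, sl])
            new_sig[c] = (float(uc @ uc) + sig_e * tr_c) / q_sizes[c]
        resid_ss = yty - float(sol @ rhs)
        new_sig_e = resid_ss / (N - rank_x)

        delta = max(
            abs(new_sig_e - sig_e),
            max(abs(new_sig[c] - sig[c]) for c in components),
        )
        sig, sig_e = new_sig, max(new_sig_e, 1e-12)
        sig = {c: max(v, 0.0) for c, v in sig.items()}
        if delta < tol * (var_y + 1e-12):
            converged = True
            break

    total = sum(sig.values()) + sig_e
    shares = {c: sig[c] / total for c in components}
    shares["residual"] = sig_e / total
    sigma2 = dict(sig)
    sigma2["residual"] = sig_e
    return ExprVarComponents(
        shares=shares,
        sigma2=sigma2,
        explained=1.0 - shares["residual"],
        n_iter=it,
        converged=converged,
    )


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-test p-value for a Pearson correlation with n pairs."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), np.finfo(float).tiny, 1.0)


def correlate_traits(
    m: AbundanceMatrix,
    adjusted_traits: pd.DataFrame,
    *,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of every (feature, trait) pair.

    Expects log2-stabilized abundances and covariate-adjusted traits.
    Returns a long DataFrame (feature_id, trait, r, p, n, significant);
    zero-variance features or traits are skipped with a warning.
    """
    if not m.log2:
        raise ValueError("correlate_traits expects log2-stabilized abundances")
    from .datatypes import COVARIATE_COLUMNS

    trait_cols = [c for c in adjusted_traits.columns if c not in COVARIATE_COLUMNS]
    samples = [s for s in m.sample_ids if s in adjusted_traits.index]
    if len(samples) < 3:
        raise ValueError("fewer than 3 shared samples")
    Xf = m.values[samples].to_numpy()           # features x n
    T = adjusted_traits.loc[samples, trait_cols].to_numpy(dtype=float)
    n = len(samples)

    f_sd = Xf.std(axis=1)
    t_sd = T.std(axis=0)
    bad_f = f_sd == 0
    bad_t = t_sd == 0
    if bad_f.any():
        warnings.warn(f"{int(bad_f.sum())} zero-variance features skipped")
    if bad_t.any():
        warnings.warn(f"{int(bad_t.sum())} zero-variance traits skipped")

    Xc = (Xf - Xf.mean(axis=1, keepdims=True))
    Tc = (T - T.mean(axis=0, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Tc) / (n * np.outer(np.where(bad_f, np.nan, f_sd),
                                      np.where(bad_t, np.nan, t_sd)))
    P = pearson_p(np.nan_to_num(R), n)

    feats = np.repeat(m.feature_ids, len(trait_cols))
    trs = np.tile(trait_cols, m.n_features)
    r_flat = R.ravel()
    out = pd.DataFrame(
        {
            "feature_id": feats,
            "trait": trs,
            "r": r_flat,
            "p": P.ravel(),
            "n": n,
        }
    )
    out = out[~out["r"].isna()].reset_index(drop=True)
    out["significant"] = out["p"] <= p_threshold
    return out


def significant_trait_counts(correlations: pd.DataFrame) -> pd.Series:
    """Number of significantly correlated traits per feature."""
    if correlations.empty:
        return pd.Series(dtype=int)
    sig = correlations[correlations["significant"].astype(bool)]
    return sig.groupby("feature_id")["trait"].nunique()


def top_trait(correlations: pd.DataFrame) -> pd.Series:
    """Per feature, the significantly correlated trait with max |r|.

    Ties break to the lexicographically smallest trait id.
    """
    if correlations.empty:
        return pd.Series(dtype=object)
    sig = correlations[correlations["significant"].astype(bool)].copy()
    if sig.empty:
        return pd.Series(dtype=object)
    sig["abs_r"] = sig["r"].abs()
    sig = sig.sort_values(["feature_id", "abs_r", "trait"],
                          ascending=[True, False, True], kind="mergesort")
    return sig.groupby("feature_id").first()["trait"]
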