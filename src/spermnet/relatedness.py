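"""Genomic relationship matrix and single-component GREML.

The GRM uses the standardized-dosage (Yang et al. 2010 / VanRaden type 2)
form averaged over SNPs::

    G_jk = (1/N) Σ_i (x_ij − 2 p_i)(x_ik − 2 p_i) / (2 p_i (1 − p_i))

GREML fits the two-component model y = Xb + u + e with u ~ N(0, G σu²) and
e ~ N(0, I σe²) by restricted maximum likelihood.  Because the model has
exactly two components, (G, I) are simultaneously diagonalized by the
eigendecomposition of G; every REML quantity (log-likelihood, score, average
information) then costs O(n) per iteration.  Updates are average-information
(AI) steps with an EM fallback whenever an AI step would leave the parameter
space; variance components are floored at 1e-8 rather than allowed negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["GRM", "VarianceComponents", "compute_grm", "greml"]

VARIANCE_FLOOR = 1e-8


@dataclass
class GRM:
    matrix: pd.DataFrame  # samples x samples
    n_snps_used: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


@dataclass
class VarianceComponents:
    """Result of a GREML fit.

    ``h2`` is σu² / (σu² + σe²); ``se_h2`` comes from the delta method on
    the inverse average-information matrix.
    """

    sigma_u2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int

    def summary(self) -> str:
        lines = [
            "GREML variance components",
            f"  sigma_u^2 (additive genetic): {self.sigma_u2:.6g}",
            f"  sigma_e^2 (residual):         {self.sigma_e2:.6g}",
            f"  h^2 = {self.h2:.4f} (SE {self.se_h2:.4f})",
            f"  REML log-likelihood: {self.loglik:.4f}",
            f"  converged: {self.converged} in {self.n_iter} iterations",
        ]
        return "\n".join(lines)


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """Standardized-dosage genomic relationship matrix.

    Missing genotypes are mean-imputed per SNP.  SNPs monomorphic after
    imputation carry no information and are skipped (with a warning);
    N in the averaging is the number of SNPs actually used.
    """
    x = geno.mean_imputed()
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_skipped = int((~poly).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} monomorphic SNPs skipped in GRM")
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    xp = x[:, poly]
    pp = p[poly]
    z = (xp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    g = z @ z.T / poly.sum()
    ids = geno.sample_ids
    return GRM(pd.DataFrame(g, index=ids, columns=ids), int(poly.sum()))


def _reml_quantities(d, yt, xt, sigma_u2, sigma_e2):
    """REML log-likelihood, residuals and weights in the eigenrotated basis."""
    w = sigma_u2 * d + sigma_e2           # eigenvalues of V
    wi = 1.0 / w
    xtw = xt * wi[:, None]
    xtvx = xt.T @ xtw                     # X' V^-1 X
    xtvy = xtw.T @ yt
    L = np.linalg.cholesky(xtvx)
    beta = np.linalg.solve(xtvx, xtvy)
    resid = yt - xt @ beta
    py = resid * wi                       # P y in rotated basis
    n, p = xt.shape
    ll = -0.5 * (
        np.log(w).sum()
        + 2.0 * np.log(np.diag(L)).sum()
        + float(resid @ py)
        + (n - p) * np.log(2.0 * np.pi)
    )
    return ll, py, wi, xtw, xtvx


def greml(
    y: np.ndarray,
    X: np.ndarray,
    G: GRM | np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Two-component AI-REML with EM safeguarding.

    Parameters
    ----------
    y
        Complete phenotype vector (length n).
    X
        Fixed-effect design, full column rank (include an intercept).
    G
        Genomic relationship matrix; clipped to PSD if needed.

    Convergence: relative change in restricted log-likelihood below ``tol``
    (default 1e-8) or ``max_iter`` iterations; non-convergence is flagged,
    not raised.  Components are constrained to >= 1e-8.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X row counts differ")
    if np.isnan(y).any():
        raise ValueError("y contains missing values; drop them first")
    g = G.to_numpy() if isinstance(G, GRM) else np.asarray(G, dtype=float)
    g = 0.5 * (g + g.T)

    d, U = np.linalg.eigh(g)
    if d.min() < -1e-8:
        warnings.warn("GRM not PSD; negative eigenvalues clipped to 0")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ X
    n, p = xt.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")

    var_y = float(np.var(y, ddof=1))
    sigma_u2 = max(0.5 * var_y, VARIANCE_FLOOR)
    sigma_e2 = max(0.5 * var_y, VARIANCE_FLOOR)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, py, wi, xtw, xtvx = _reml_quantities(d, yt, xt, sigma_u2, sigma_e2)

        # tr(P A) = tr(V^-1 A) − tr((X'V^-1X)^-1 X'V^-1 A V^-1 X) with A
        # diagonal (d or 1) in the rotated basis
        xtvx_inv = np.linalg.inv(xtvx)

        def tr_P(a_diag):
            t1 = float((wi * a_diag).sum())
            m = xtw.T * a_diag  # p x n
            t2 = float(np.einsum("ij,ji->", xtvx_inv, m @ xtw))
            return t1 - t2

        ones = np.ones_like(d)
        # score: dl/dσ²_a = −0.5 [tr(P A_a) − y'P A_a P y]
        yPAPy_u = float((d * py * py).sum())
        yPAPy_e = float((py * py).sum())
        score_u = -0.5 * (tr_P(d) - yPAPy_u)
        score_e = -0.5 * (tr_P(ones) - yPAPy_e)

        # average information: AI_ab = 0.5 y' P A_a P A_b P y
        def P_apply(v):
            # P v = V^-1 v − V^-1 X (X'V^-1X)^-1 X' V^-1 v   (rotated basis)
            vv = wi * v
            return vv - xtw @ (xtvx_inv @ (xtw.T @ v))

        pu = P_apply(d * py)
        pe = P_apply(py)
        ai = 0.5 * np.array(
            [
                [float((d * py) @ pu), float((d * py) @ pe)],
                [float((d * py) @ pe), float(py @ pe)],
            ]
        )
        score = np.array([score_u, score_e])

        step_ok = False
        try:
            delta = np.linalg.solve(ai, score)
            new_u = sigma_u2 + delta[0]
            new_e = sigma_e2 + delta[1]
            # negative proposals are clamped to the floor (boundary
            # solutions), mirroring GCTA's constrained AI-REML; a wild or
            # non-finite step falls back to EM
            if np.all(np.isfinite([new_u, new_e])) and new_e > 0:
                step_ok = True
        except np.linalg.LinAlgError:
            pass

        if not step_ok:
            # EM fallback (guaranteed to stay in the parameter space)
            new_u = sigma_u2 + (sigma_u2**2 / n) * (yPAPy_u - tr_P(d))
            new_e = sigma_e2 + (sigma_e2**2 / n) * (yPAPy_e - tr_P(ones))

        prev_u, prev_e = sigma_u2, sigma_e2
        sigma_u2 = max(float(new_u), VARIANCE_FLOOR)
        sigma_e2 = max(float(new_e), VARIANCE_FLOOR)

        total = sigma_u2 + sigma_e2
        param_change = max(abs(sigma_u2 - prev_u), abs(sigma_e2 - prev_e)) / total
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0) or param_change < 1e-10:
            converged = True
            break
        ll_old = ll

    ll, py, wi, xtw, xtvx = _reml_quantities(d, yt, xt, sigma_u2, sigma_e2)
    if not converged:
        warnings.warn("GREML did not converge; estimates flagged")

    # SE of h2 via delta method on inv(AI)
    xtvx_inv = np.linalg.inv(xtvx)

    def P_apply(v):
        return wi * v - xtw @ (xtvx_inv @ (xtw.T @ v))

    pu = P_apply(d * py)
    pe = P_apply(py)
    ai = 0.5 * np.array(
        [
            [float((d * py) @ pu), float((d * py) @ pe)],
            [float((d * py) @ pe), float(py @ pe)],
        ]
    )
    total = sigma_u2 + sigma_e2
    h2 = sigma_u2 / total
    try:
        cov = np.linalg.inv(ai)
        grad = np.array([sigma_e2, -sigma_u2]) / total**2
        var_h2 = float(grad @ cov @ grad)
        se_h2 = float(np.sqrt(max(var_h2, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate AI
        se_h2 = float("nan")

    return VarianceComponents(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        h2=h2,
        se_h2=se_h2,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
    )
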