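"""Partial-correlation-with-information-theory (PCIT) edge filtering.

PCIT decides which entries of a correlation matrix reflect meaningful
direct association.  For every ordered trio (x, y, z) it computes the three
first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

and a data-driven tolerance eps = mean of |partial / direct| over the three
pairs of the trio.  The edge (x, y) is eliminated when some z makes both
|r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz| (ties eliminate).  Edges
that survive and whose plain correlation is significant (two-sided t-test
P <= 0.05) form the reported network.  With exactly two features there are
no trios and every edge survives the elimination step.

The production implementation vectorizes over z (O(n) passes of O(n^2)
work); ``pcit_filter_reference`` is a deliberately naive triple loop kept
as an independent oracle for tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import pearson_p

__all__ = [
    "CorrelationNetworkResult",
    "pcit_filter",
    "pcit_filter_reference",
    "mirna_gene_edges",
]

_TINY = 1e-12


@dataclass
class CorrelationNetworkResult:
    """Full correlation matrix plus the PCIT decision masks."""

    nodes: list[str]
    corr: np.ndarray         # symmetric r matrix
    kept: np.ndarray         # bool mask: survived trio elimination
    p: np.ndarray            # correlation p-values
    significant: np.ndarray  # kept AND p <= threshold

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (
                        self.nodes[i],
                        self.nodes[j],
                        self.corr[i, j],
                        self.p[i, j],
                        bool(self.kept[i, j]),
                        bool(self.significant[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "r", "p", "kept", "significant"]
        )

    def significant_pairs(self) -> list[tuple[str, str]]:
        n = len(self.nodes)
        return [
            (self.nodes[i], self.nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if self.significant[i, j]
        ]


def _corr_and_p(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_obs = data.shape[1]
    r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    p = pearson_p(r, n_obs)
    np.fill_diagonal(p, 1.0)
    return r, p


def _drop_constant(data: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    sd = data.std(axis=1)
    bad = sd == 0
    if bad.any():
        dropped = [names[i] for i in np.nonzero(bad)[0]]
        warnings.warn(f"constant features excluded from PCIT: {dropped}")
        data = data[~bad]
        names = [nm for nm, b in zip(names, bad) if not b]
    return data, names


def pcit_filter(
    data: np.ndarray | pd.DataFrame,
    *,
    p_threshold: float = 0.05,
    significance_after_pcit: bool = True,
) -> CorrelationNetworkResult:
    """Run PCIT on a features x observations matrix.

    Needs >= 2 features and >= 3 observations.  Constant features are
    excluded with a warning.  ``significance_after_pcit=False`` applies the
    correlation significance screen before trio elimination instead of
    after (the elimination step itself is unchanged; only which edges are
    reported as significant can differ at the margin).
    """
    if isinstance(data, pd.DataFrame):
        names = [str(i) for i in data.index]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        names = [f"f{i}" for i in range(x.shape[0])]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 features")
    if x.shape[1] < 3:
        raise ValueError("need >= 3 observations")
    x, names = _drop_constant(x, names)
    n = x.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 non-constant features")

    r, p = _corr_and_p(x)
    kept = np.ones((n, n), dtype=bool)
    np.fill_diagonal(kept, False)

    if n >= 3:
        absr = np.abs(r)
        eliminated = np.zeros((n, n), dtype=bool)
        for z in range(n):
            rz = r[:, z]
            den_z = np.sqrt(np.clip(1.0 - rz**2, _TINY, None))   # sqrt(1 - r_xz^2)
            den_xy = np.sqrt(np.clip(1.0 - r**2, _TINY, None))   # sqrt(1 - r_xy^2)

            # the trio (x, y, z) has pairs (x,y), (x,z), (y,z); partials:
            p_xy_z = (r - np.outer(rz, rz)) / np.outer(den_z, den_z)
            # r_xz.y over (x, y): (r_xz - r_xy r_yz) / sqrt((1-r_xy^2)(1-r_yz^2))
            p_xz_y = (rz[:, None] - r * rz[None, :]) / (den_xy * den_z[None, :])

            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_xy = np.where(absr >= _TINY, np.abs(p_xy_z) / absr, np.nan)
                dir_xz = absr[:, z][:, None]
                ratio_xz = np.where(dir_xz >= _TINY, np.abs(p_xz_y) / dir_xz, np.nan)
                ratio_yz = ratio_xz.T  # role symmetry: (y,z) given x

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                eps = np.nanmean(np.stack([ratio_xy, ratio_xz, ratio_yz]), axis=0)
            eps = np.nan_to_num(eps, nan=1.0)

            lim_xz = np.abs(eps) * absr[:, z][:, None]   # |eps * r_xz|
            lim_yz = np.abs(eps) * absr[:, z][None, :]   # |eps * r_yz|
            elim_z = (absr <= lim_xz) & (absr <= lim_yz)
            elim_z[z, :] = False
            elim_z[:, z] = False
            np.fill_diagonal(elim_z, False)
            eliminated |= elim_z
        eliminated = eliminated | eliminated.T
        kept &= ~eliminated

    if not significance_after_pcit:
        # screen first: non-significant correlations are not edges at all
        kept &= p <= p_threshold
    significant = kept & (p <= p_threshold)
    return CorrelationNetworkResult(names, r, kept, p, significant)


def pcit_filter_reference(
    data: np.ndarray | pd.DataFrame, *, p_threshold: float = 0.05
) -> CorrelationNetworkResult:
    """Naive O(n^3) trio-elimination oracle (kept independent of the
    vectorized implementation; used for equivalence testing)."""
    if isinstance(data, pd.DataFrame):
        names = [str(i) for i in data.index]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        names = [f"f{i}" for i in range(x.shape[0])]
    x, names = _drop_constant(x, names)
    n = x.shape[0]
    r, p = _corr_and_p(x)
    kept = np.ones((n, n), dtype=bool)
    np.fill_diagonal(kept, False)

    def partial(a, b, c):
        den = (1.0 - r[a, c] ** 2) * (1.0 - r[b, c] ** 2)
        return (r[a, b] - r[a, c] * r[b, c]) / np.sqrt(max(den, _TINY))

    for i in range(n):
        for j in range(i + 1, n):
            for z in range(n):
                if z == i or z == j:
                    continue
                ratios = []
                for (a, b, c) in ((i, j, z), (i, z, j), (j, z, i)):
                    direct = abs(r[a, b])
                    if direct >= _TINY:
                        ratios.append(abs(partial(a, b, c)) / direct)
                eps = float(np.mean(ratios)) if ratios else 1.0
                if abs(r[i, j]) <= abs(eps * r[i, z]) and abs(r[i, j]) <= abs(
                    eps * r[j, z]
                ):
                    kept[i, j] = kept[j, i] = False
                    break
    significant = kept & (p <= p_threshold)
    return CorrelationNetworkResult(names, r, kept, p, significant)


def mirna_gene_edges(
    mirna,
    genes,
    *,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Significant *negative* miRNA-gene edges from PCIT on the stacked
    matrix.

    Both abundance matrices must be log2-stabilized and share samples.
    Returns a DataFrame (mirna_id, gene_id, r, p) with r < 0 only.
    """
    from .datatypes import AbundanceMatrix

    if isinstance(mirna, AbundanceMatrix):
        if not (mirna.log2 and genes.log2):
            raise ValueError("expects log2-stabilized abundances")
        shared = [s for s in mirna.sample_ids if s in genes.sample_ids]
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared samples")
        m_vals = mirna.values[shared]
        g_vals = genes.values[shared]
    else:  # plain DataFrames
        shared = [s for s in mirna.columns if s in genes.columns]
        m_vals = mirna[shared]
        g_vals = genes[shared]

    mir_ids = [str(i) for i in m_vals.index]
    gene_ids = [str(i) for i in g_vals.index]
    stacked = pd.concat([m_vals, g_vals])
    res = pcit_filter(stacked, p_threshold=p_threshold)
    name_to_pos = {nm: k for k, nm in enumerate(res.nodes)}

    rows = []
    for mi in mir_ids:
        if mi not in name_to_pos:
            continue
        a = name_to_pos[mi]
        for gi in gene_ids:
            if gi not in name_to_pos:
                continue
            b = name_to_pos[gi]
            if res.significant[a, b] and res.corr[a, b] < 0:
                rows.append((mi, gi, res.corr[a, b], res.p[a, b]))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "r", "p"])
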