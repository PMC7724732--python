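"""Shared in-memory containers for the pipeline.

Conventions used throughout the package:

* genotypes are additive dosages in {0, 1, 2} counting copies of allele ``a1``,
  with ``NaN`` marking a missing call;
* all genomic coordinates are 1-based and inclusive;
* abundance matrices are features (rows) x samples (columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AbundanceMatrix",
    "Network",
    "COVARIATE_COLUMNS",
]

#: covariate columns carried by every trait table
COVARIATE_COLUMNS = ("farm", "season_year", "age")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix plus its SNP map.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id with one float column per SNP;
        values in {0, 1, 2} or NaN for missing.
    snp_map
        DataFrame with columns ``snp_id, chrom, bp, a1, a2`` aligned with
        (and in the same order as) the dosage columns.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snp_map["snp_id"]):
            raise ValueError("dosage columns and snp_map rows are not aligned")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in map")
        if (self.snp_map["bp"] < 1).any():
            raise ValueError("bp positions must be >= 1 (1-based)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def allele_freq(self) -> pd.Series:
        """Frequency of allele a1, ignoring missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Dosage array with missing entries replaced by the SNP mean."""
        x = self.dosages.to_numpy(dtype=float, copy=True)
        col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
        return x

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = [s for s in snp_ids]
        return GenotypeMatrix(
            self.dosages.loc[:, ids],
            self.snp_map.set_index("snp_id").loc[ids].reset_index(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)], self.snp_map.copy())


@dataclass
class AbundanceMatrix:
    """RNA abundance matrix (genes or miRNAs x samples).

    ``kind`` is ``"mRNA"`` (FPKM units) or ``"miRNA"`` (CPM units);
    ``log2`` records whether values have been log2(x + pseudocount)
    stabilized already.
    """

    values: pd.DataFrame
    kind: str = "mRNA"
    log2: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mRNA", "miRNA"):
            raise ValueError(f"unknown abundance kind {self.kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if not self.log2 and (self.values.to_numpy() < 0).any():
            raise ValueError("raw abundances must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def _edge_key(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self edge {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class Network:
    """Undirected network of genes and miRNAs with typed, annotated nodes.

    nodes: id -> attribute dict (``type`` in {gene, miRNA}; annotations
    ``n_traits``, ``top_trait``, ``tf_class``, ``in_shared`` filled in by the
    network-assembly stage).
    edges: sorted (a, b) tuple -> dict with ``weight`` (correlation r) and
    ``provenance`` (set of tags from {snp, rna, mirna, shared}).
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add_node(self, node_id: str, node_type: str = "gene", **attrs) -> None:
        d = self.nodes.setdefault(node_id, {"type": node_type})
        d.update(attrs)

    def add_edge(self, a: str, b: str, weight: float, provenance: str) -> None:
        key = _edge_key(a, b)
        for n in key:
            self.nodes.setdefault(n, {"type": "gene"})
        e = self.edges.setdefault(key, {"weight": weight, "provenance": set()})
        e["provenance"].add(provenance)

    def has_edge(self, a: str, b: str) -> bool:
        return _edge_key(a, b) in self.edges

    def neighbors(self, node_id: str) -> list[str]:
        out = []
        for (a, b) in self.edges:
            if a == node_id:
                out.append(b)
            elif b == node_id:
                out.append(a)
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network({self.n_nodes} nodes, {self.n_edges} edges)"
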