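"""Assembly of the SNP co-association, RNA co-abundance, shared and final
gene networks.

The SNP network runs PCIT over AWM rows (each gene's standardized effects
across traits are its profile); the RNA network runs PCIT over log2 gene
abundances across samples.  The *shared* network is their intersection
(nodes and unordered edge pairs present in both) and is taken as the
high-confidence core.  The *final* network augments the shared core with
genes whose abundance correlates with more than three traits, the RNA-
network edges of those genes (bringing in their partner nodes), and
significant negative miRNA-gene edges touching final-network genes.  Node
annotations carry the number of significantly correlated traits, the
top-correlated trait, the TF class and shared-network membership.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .datatypes import AbundanceMatrix, Network
from .expression import significant_trait_counts, top_trait
from .pcit import CorrelationNetworkResult, pcit_filter

__all__ = [
    "build_snp_network",
    "build_rna_network",
    "intersect_networks",
    "build_final_network",
    "annotate_nodes",
    "network_summary",
]


def _network_from_pcit(res: CorrelationNetworkResult, provenance: str) -> Network:
    net = Network()
    n = len(res.nodes)
    for name in res.nodes:
        net.add_node(name, "gene")
    for i in range(n):
        for j in range(i + 1, n):
            if res.significant[i, j]:
                net.add_edge(res.nodes[i], res.nodes[j], float(res.corr[i, j]), provenance)
    return net


def build_snp_network(awm) -> Network:
    """PCIT over AWM gene rows (observations = traits); provenance "snp"."""
    mat = awm.matrix
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 traits for PCIT trios")
    res = pcit_filter(mat)
    return _network_from_pcit(res, "snp")


def build_rna_network(genes: AbundanceMatrix) -> Network:
    """PCIT over filtered log2 gene abundances; provenance "rna"."""
    if not genes.log2:
        raise ValueError("RNA network expects log2-stabilized abundances")
    res = pcit_filter(genes.values)
    return _network_from_pcit(res, "rna")


def intersect_networks(snp_net: Network, rna_net: Network) -> Network:
    """Shared network: nodes and edges present in both input networks.

    Edge weights come from the RNA network (abundance correlations);
    ``in_shared`` is set on every surviving node.
    """
    shared = Network()
    common_edges = set(snp_net.edges) & set(rna_net.edges)
    if not common_edges:
        warnings.warn("networks share no edges; shared network is empty")
    for (a, b) in sorted(common_edges):
        w = rna_net.edges[(a, b)]["weight"]
        shared.add_edge(a, b, w, "shared")
    for node in shared.nodes:
        shared.nodes[node]["in_shared"] = True
    return shared


def build_final_network(
    shared: Network,
    rna_net: Network,
    trait_correlations: pd.DataFrame,
    mirna_edges: pd.DataFrame,
    tf_table: pd.DataFrame | None = None,
    *,
    min_traits_to_add: int = 3,
) -> Network:
    """Merge the shared core with highly trait-correlated genes and miRNAs.

    Added genes are those absent from the shared network whose abundance
    correlates with strictly more than ``min_traits_to_add`` traits; their
    RNA-network edges (and the partner genes those edges introduce) come
    along.  Significant negative miRNA edges touching any final-network
    gene are appended last.  All nodes get annotations.
    """
    final = Network()
    for (a, b), e in shared.edges.items():
        final.add_edge(a, b, e["weight"], "shared")
    for node in shared.nodes:
        final.add_node(node, shared.nodes[node].get("type", "gene"))

    counts = significant_trait_counts(trait_correlations)
    added = [
        g
        for g in counts.index
        if counts[g] > min_traits_to_add
        and g in rna_net.nodes
        and g not in shared.nodes
    ]
    for g in sorted(added):
        final.add_node(g, "gene")
        for (a, b), e in rna_net.edges.items():
            if g in (a, b):
                final.add_edge(a, b, e["weight"], "rna")

    # miRNA edges restricted to genes already in the final network
    for row in mirna_edges.itertuples(index=False):
        if row.gene_id in final.nodes:
            final.add_node(row.mirna_id, "miRNA")
            final.add_edge(row.mirna_id, row.gene_id, float(row.r), "mirna")

    annotate_nodes(final, trait_correlations, tf_table, shared_nodes=set(shared.nodes))
    return final


def annotate_nodes(
    net: Network,
    trait_correlations: pd.DataFrame,
    tf_table: pd.DataFrame | None = None,
    *,
    shared_nodes: set[str] | None = None,
) -> None:
    """Fill n_traits / top_trait / tf_class / in_shared on every node."""
    counts = significant_trait_counts(trait_correlations)
    tops = top_trait(trait_correlations)
    tf_map: dict[str, str] = {}
    if tf_table is not None and "tf_class" in tf_table.columns:
        tf_map = dict(zip(tf_table["gene_id"].astype(str), tf_table["tf_class"].astype(str)))
    shared_nodes = shared_nodes or set()
    for node, attrs in net.nodes.items():
        attrs["n_traits"] = int(counts.get(node, 0))
        attrs["top_trait"] = str(tops.get(node, ""))
        attrs["tf_class"] = tf_map.get(node, "none")
        attrs["in_shared"] = node in shared_nodes


def network_summary(named_networks: dict[str, Network]) -> pd.DataFrame:
    """Node/edge counts per network stage (snp, rna, shared, final)."""
    rows = [
        {"network": name, "n_nodes": net.n_nodes, "n_edges": net.n_edges}
        for name, net in named_networks.items()
    ]
    return pd.DataFrame(rows)
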