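"""Readers and writers for the external formats the pipeline touches.

Genotypes travel as PLINK *text* ped/map pairs; tabular data (phenotypes,
abundances, annotation, association scans, edge lists) as UTF-8
tab-delimited files with a header row; networks as Cytoscape SIF plus
GraphML with node attributes.  All genomic coordinates are 1-based
inclusive.  Writers emit rows in a deterministic order so identical inputs
give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, GenotypeMatrix, Network

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_trait_table",
    "write_trait_table",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_network_sif",
    "write_network_graphml",
    "write_network_edges",
    "read_network_edges",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "biotype", "tf_class"]


# ---------------------------------------------------------------------------
# PLINK text ped/map


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text ped/map pair into dosages of allele a1.

    The a1 allele per SNP is the first non-missing allele encountered
    unless the map file carries explicit ``a1``/``a2`` columns (columns 5-6).
    ``0`` alleles mark missing genotypes.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed map line: {line!r}")
            map_rows.append(parts)
    n_snps = len(map_rows)

    sample_ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            expected = 6 + 2 * n_snps
            if len(parts) != expected:
                raise ValueError(
                    f"ped line {lineno}: expected {expected} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    a1_list, a2_list = [], []
    for j, row in enumerate(map_rows):
        if len(row) >= 6:
            a1_list.append(row[4])
            a2_list.append(row[5])
        else:
            seen = []
            for alleles in allele_rows:
                for a in (alleles[2 * j], alleles[2 * j + 1]):
                    if a != "0" and a not in seen:
                        seen.append(a)
            a1_list.append(seen[0] if seen else "0")
            a2_list.append(seen[1] if len(seen) > 1 else (seen[0] if seen else "0"))

    dosages = np.full((len(sample_ids), n_snps), np.nan)
    for i, alleles in enumerate(allele_rows):
        for j in range(n_snps):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == a1_list[j]) + (b == a1_list[j])

    snp_map = pd.DataFrame(
        {
            "snp_id": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "bp": [int(r[3]) for r in map_rows],
            "a1": a1_list,
            "a2": a2_list,
        }
    )
    dos = pd.DataFrame(dosages, index=sample_ids, columns=snp_map["snp_id"].tolist())
    return GenotypeMatrix(dos, snp_map)


def write_plink_text(geno: GenotypeMatrix, ped_path, map_path) -> None:
    """Write genotypes as a PLINK text ped/map pair (a1/a2 in map cols 5-6)."""
    m = geno.snp_map
    with open(map_path, "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\t{row.a1}\t{row.a2}\n")
    dos = geno.dosages.to_numpy()
    a1 = m["a1"].to_numpy()
    a2 = m["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j in range(geno.n_snps):
                d = dos[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# tab-delimited tables


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    for c in ("farm", "season_year", "age"):
        if c in df.columns:
            df[c] = df[c].astype(str)
    return df


def write_abundance_tsv(m: AbundanceMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_abundance_tsv(path, kind: str = "mRNA", log2: bool = False) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceMatrix(df, kind=kind, log2=log2)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("annotation rows with start > end")
    return df


# ---------------------------------------------------------------------------
# networks


def write_network_sif(net: Network, path) -> None:
    """SIF export: one ``nodeA interacts nodeB`` line per edge."""
    if net.n_nodes == 0:
        raise ValueError("refusing to write an empty network")
    with open(path, "w") as fh:
        for (a, b) in sorted(net.edges):
            fh.write(f"{a}\tinteracts\t{b}\n")
        connected = {n for e in net.edges for n in e}
        for n in sorted(net.nodes):
            if n not in connected:
                fh.write(f"{n}\n")


def _to_nx(net: Network) -> nx.Graph:
    g = nx.Graph()
    for node_id in sorted(net.nodes):
        attrs = net.nodes[node_id]
        g.add_node(
            node_id,
            type=attrs.get("type", "gene"),
            n_traits=int(attrs.get("n_traits", 0)),
            top_trait=str(attrs.get("top_trait", "")),
            tf_class=str(attrs.get("tf_class", "none")),
            in_shared=bool(attrs.get("in_shared", False)),
        )
    for (a, b) in sorted(net.edges):
        e = net.edges[(a, b)]
        g.add_edge(
            a,
            b,
            weight=float(e.get("weight", 0.0)),
            provenance=",".join(sorted(e.get("provenance", set()))),
        )
    return g


def write_network_graphml(net: Network, path) -> None:
    """GraphML export carrying the node annotations the analysis fills in."""
    if net.n_nodes == 0:
        raise ValueError("refusing to write an empty network")
    nx.write_graphml(_to_nx(net), path)


def write_network_edges(net: Network, path) -> None:
    """Edge-list TSV (node_a, node_b, weight, provenance), sorted rows."""
    rows = [
        (a, b, net.edges[(a, b)]["weight"], ",".join(sorted(net.edges[(a, b)]["provenance"])))
        for (a, b) in sorted(net.edges)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "provenance"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_network_edges(path) -> Network:
    df = pd.read_csv(path, sep="\t")
    net = Network()
    for row in df.itertuples(index=False):
        for tag in str(row.provenance).split(","):
            net.add_edge(str(row.node_a), str(row.node_b), float(row.weight), tag)
    return net
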