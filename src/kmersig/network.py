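"""Normalized gene-sharing networks from pairwise homolog-count tables.

Nodes are genomes; an edge carries the raw number of shared homologous
genes of a pair and a normalized weight obtained by dividing the count by
the smaller genome of the pair (by default its length in kilobases).  The
upstream all-vs-all protein comparison is consumed as a table, never run
here; its search parameters can be recorded as provenance metadata.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["genome_a", "genome_b", "shared_gene_count"]


def element_category(element_type: str, length_bp: int) -> str:
    """Node category: cell, megaplasmid (>150 kb), large plasmid
    (100-150 kb), small plasmid, or virus."""
    if element_type == "cell":
        return "cell"
    if element_type in ("virus", "provirus"):
        return "virus"
    if element_type == "plasmid":
        if length_bp > 150_000:
            return "megaplasmid"
        if length_bp >= 100_000:
            return "large plasmid"
        return "small plasmid"
    raise ValueError(f"unknown element type {element_type!r}")


def read_homolog_table(
    source: str | Path | pd.DataFrame, known_ids=None
) -> pd.DataFrame:
    """Read and validate a pairwise shared-gene-count table.

    Rejects duplicate unordered pairs, self pairs, negative counts, and
    (when ``known_ids`` is given) unknown genome ids.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"homolog table must have column {col!r}")
    if len(df) == 0:
        logger.warning("empty homolog table: the network will have no edges")
        return df.copy()
    if (df["shared_gene_count"] < 0).any():
        raise ValueError("negative shared-gene counts")
    if (df["genome_a"] == df["genome_b"]).any():
        raise ValueError("self pairs are not allowed")
    key = df.apply(lambda r: tuple(sorted((r.genome_a, r.genome_b))), axis=1)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(f"duplicate unordered pair {dup}")
    if known_ids is not None:
        ids = set(known_ids)
        unknown = set(df["genome_a"]) | set(df["genome_b"]) - ids
        unknown -= ids
        if unknown:
            raise ValueError(f"unknown genome ids in homolog table: {sorted(unknown)[:5]}")
    return df.copy()


def build_network(
    pairs: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "kb",
    provenance: dict | None = None,
) -> nx.Graph:
    """Weighted gene-sharing graph over all genomes in ``metadata``.

    ``mode`` selects the normalization denominator of each pair: the
    smaller genome's length in kilobases (``kb``, default), in bases
    (``bp``), or its gene count (``genes``, requires an ``n_genes``
    metadata column).  Isolated genomes are kept as nodes.
    """
    if mode not in ("kb", "bp", "genes"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    G = nx.Graph(normalization=mode, **(provenance or {}))
    for gid, row in meta.iterrows():
        G.add_node(
            gid,
            category=element_category(row["type"], int(row["length_bp"])),
            length_bp=int(row["length_bp"]),
        )
    for row in pairs.itertuples(index=False):
        a, b = row.genome_a, row.genome_b
        for gid in (a, b):
            if gid not in G:
                raise ValueError(f"genome {gid} missing from metadata")
        if mode == "genes":
            denom = min(meta.loc[a, "n_genes"], meta.loc[b, "n_genes"])
        else:
            denom = min(meta.loc[a, "length_bp"], meta.loc[b, "length_bp"])
            if mode == "kb":
                denom = denom / 1000.0
        if denom == 0:
            raise ValueError(f"zero normalization denominator for pair ({a}, {b})")
        G.add_edge(
            a, b, raw_count=int(row.shared_gene_count),
            weight=float(row.shared_gene_count) / float(denom),
        )
    return G


def filter_edges(G: nx.Graph, threshold: float = 0.1) -> nx.Graph:
    """Drop edges with weight strictly below ``threshold``; nodes are kept."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    H = G.copy()
    weak = [(a, b) for a, b, w in H.edges(data="weight") if w < threshold]
    H.remove_edges_from(weak)
    H.graph["edge_filter"] = threshold
    return H


def category_edge_stats(G: nx.Graph, normalization: str = "pooled") -> pd.DataFrame:
    """Edge counts between category pairs, normalized by category sizes.

    With the default ``pooled`` convention the count of edges between
    categories X != Y is divided by |X| + |Y|, and the within-category
    count by |X|.  The ``per_pair`` convention divides by |X| * |Y|
    (within: |X| * (|X| - 1) / 2) instead.  Empty categories are skipped.
    """
    if normalization not in ("pooled", "per_pair"):
        raise ValueError(f"unknown normalization {normalization!r}")
    cats: dict[str, list] = {}
    for node, c in G.nodes(data="category"):
        if c is None:
            raise ValueError(f"node {node} has no category")
        cats.setdefault(c, []).append(node)
    counts: dict[tuple[str, str], int] = {}
    for a, b in G.edges():
        ca, cb = G.nodes[a]["category"], G.nodes[b]["category"]
        key = tuple(sorted((ca, cb)))
        counts[key] = counts.get(key, 0) + 1
    rows = []
    names = sorted(cats)
    for i, x in enumerate(names):
        for y in names[i:]:
            n_edges = counts.get((x, y), 0)
            nx_, ny = len(cats[x]), len(cats[y])
            if normalization == "pooled":
                denom = nx_ if x == y else nx_ + ny
            else:
                denom = nx_ * (nx_ - 1) / 2 if x == y else nx_ * ny
            if denom == 0:
                logger.warning("skipping category pair (%s, %s): empty denominator", x, y)
                continue
            rows.append(
                {
                    "category_a": x,
                    "category_b": y,
                    "n_edges": n_edges,
                    "stat": n_edges / denom,
                }
            )
    return pd.DataFrame(rows, columns=["category_a", "category_b", "n_edges", "stat"])


def write_edge_table(G: nx.Graph, path: str | Path) -> None:
    rows = [
        {"genome_a": a, "genome_b": b, "raw_count": d["raw_count"], "weight": d["weight"]}
        for a, b, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["genome_a", "genome_b", "raw_count", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))
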