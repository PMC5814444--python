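"""Codon-typed network motif enumeration.

Two kinds of motif are counted in each genome network:

* **ThNM** — a three-node clique (triangle), typed by the unordered
  multiset of its members' codon labels; 20 types over labels {0,1,2,3}.
* **TNM** — an edge whose endpoints survive after *removing every node
  that participates in a triangle*, typed by the unordered pair of
  endpoint labels; 10 types over {0,1,2,3}. Under this node-subtraction
  rule a pendant edge touching a triangle node is not a TNM; the
  alternative edge-subtraction rule (drop only triangle edges) is
  available via ``tnm_rule``.

Triangles inside larger cliques are counted once per triangle (a
k-clique contributes C(k,3) of them).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cooccurrence import GenomeNetwork

TNM_RULES = ("node_subtraction", "edge_subtraction")


def motif_type_space(order: int, alphabet_size: int = 4) -> list[str]:
    """All canonical label multisets of the given order, rendered "a-b" / "a-b-c".

    The count is C(alphabet_size + order - 1, order): 10 two-node and 20
    three-node types over the four codon labels.
    """
    if order not in (2, 3):
        raise ValueError("motif order must be 2 or 3")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    return [
        "-".join(str(v) for v in combo)
        for combo in combinations_with_replacement(range(alphabet_size), order)
    ]


def canonical_type(labels: tuple[int, ...]) -> str:
    """Canonical type string: labels sorted ascending, joined by '-'."""
    return "-".join(str(v) for v in sorted(labels))


def find_triangles(graph: nx.Graph) -> set[tuple[int, int, int]]:
    """Every unordered node triple with all three edges present.

    Uses ordered neighbor intersection so each triangle is reported once;
    overlapping triangles are all reported.
    """
    order = {node: k for k, node in enumerate(graph.nodes)}
    triangles: set[tuple[int, int, int]] = set()
    for u, v in graph.edges:
        if order[u] > order[v]:
            u, v = v, u
        common = set(graph[u]) & set(graph[v])
        for w in common:
            if order[w] > order[v]:
                triangles.add(tuple(sorted((u, v, w))))
    return triangles


@dataclass
class MotifCensus:
    """Typed motif counts for one genome network."""

    group: str
    sample_id: str
    tnm_counts: Counter = field(default_factory=Counter)
    thnm_counts: Counter = field(default_factory=Counter)
    clique_nodes: set = field(default_factory=set)
    n_triangles: int = 0

    @property
    def total_tnm(self) -> int:
        return sum(self.tnm_counts.values())

    @property
    def total_thnm(self) -> int:
        return sum(self.thnm_counts.values())


def census(
    network: GenomeNetwork,
    tnm_rule: str = "node_subtraction",
    label_attr: str = "label",
) -> MotifCensus:
    """Count TNMs and ThNMs of one labeled network by canonical type."""
    if tnm_rule not in TNM_RULES:
        raise ValueError(f"tnm_rule must be one of {TNM_RULES}")
    G = network.graph
    triangles = find_triangles(G)
    clique_nodes = set().union(*map(set, triangles)) if triangles else set()

    def lab(node) -> int:
        return int(G.nodes[node].get(label_attr, 0))

    thnm: Counter = Counter()
    for tri in triangles:
        thnm[canonical_type(tuple(lab(n) for n in tri))] += 1

    tnm: Counter = Counter()
    if tnm_rule == "node_subtraction":
        kept = G.subgraph(set(G.nodes) - clique_nodes)
        tnm_edges = kept.edges
    else:
        tri_edges = {
            tuple(sorted(e))
            for tri in triangles
            for e in combinations(tri, 2)
        }
        tnm_edges = [
            e for e in G.edges if tuple(sorted(e)) not in tri_edges
        ]
    for u, v in tnm_edges:
        tnm[canonical_type((lab(u), lab(v)))] += 1

    return MotifCensus(
        group=network.group,
        sample_id=network.sample_id,
        tnm_counts=tnm,
        thnm_counts=thnm,
        clique_nodes=clique_nodes,
        n_triangles=len(triangles),
    )


def group_census(
    censuses: list[MotifCensus], alphabet_size: int = 4
) -> pd.DataFrame:
    """Per-type totals, means and sds over an ensemble of censuses.

    Every type in the full motif spaces appears, zero-filled, so real and
    randomized ensembles tabulate over identical keys.
    """
    if not censuses:
        raise ValueError("need at least one census")
    rows = []
    for scope, order, getter in (
        ("TNM", 2, lambda c: c.tnm_counts),
        ("ThNM", 3, lambda c: c.thnm_counts),
    ):
        for mtype in motif_type_space(order, alphabet_size):
            counts = np.array([getter(c).get(mtype, 0) for c in censuses], dtype=float)
            rows.append(
                {
                    "type": mtype,
                    "scope": scope,
                    "total": int(counts.sum()),
                    "mean": float(counts.mean()),
                    "sd": float(counts.std(ddof=0)),
                }
            )
    return pd.DataFrame(rows, columns=["type", "scope", "total", "mean", "sd"])


def write_group_census(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
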