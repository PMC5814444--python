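"""Nucleotide co-occurrence scoring and per-genome network construction.

For two states x at position i and y at position j observed over the M
genomes of a group, the co-occurrence score is

    CO_ij = f(x_i y_j)^2 / (f(x_i) f(y_j))
          = N(x_i y_j)^2 / (N(x_i) N(y_j)),

where f are occurrence frequencies (counts over M; M cancels). CO = 1
exactly when the carriers of the two states are the same set of genomes
(perfect co-segregation). Perfect pairs define edges: genome g's network
contains edge (i, j) iff some perfect state pair (x, y) satisfies
g[i] = x and g[j] = y, so each of the M genomes has its own network.

Perfection is tested on integer counts (N(xy)^2 == N(x) N(y)), never on
floats, because the threshold is exact.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment_io import AlignedGroup
from .annotation import CodonLabeling
from .variome import Variome

StatePair = tuple[int, str, int, str]


def co_occurrence_score(
    pair_count: int, count_x: int, count_y: int, M: int
) -> float:
    """CO score from integer counts; equals (f(xy)/M-form)^2/(f(x) f(y))."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if count_x < 1 or count_y < 1:
        raise ValueError("state counts must be >= 1 for a defined score")
    if not 0 <= pair_count <= min(count_x, count_y):
        raise ValueError(
            f"pair_count {pair_count} exceeds min(count_x, count_y)="
            f"{min(count_x, count_y)}"
        )
    return pair_count * pair_count / (count_x * count_y)


@dataclass
class COPairTable:
    """State-pair co-occurrence scores and the perfect-pair set for one group.

    ``entries`` maps (i, x, j, y) with i < j to
    (pair_count, count_x, count_y, score) for every state pair co-observed
    at least once. ``perfect_pairs`` holds the entries with score exactly 1
    that pass the configured filters.
    """

    group: str
    M: int
    entries: dict[StatePair, tuple[int, int, int, float]]
    perfect_pairs: set[StatePair]
    carriers: dict[tuple[int, str], frozenset[int]] = field(default_factory=dict)
    variant_only: bool = True
    min_carriers: int = 1

    @property
    def perfect_positions(self) -> set[int]:
        return {i for (i, _, j, _) in self.perfect_pairs} | {
            j for (_, _, j, _) in self.perfect_pairs
        }


def state_carriers(
    group: AlignedGroup, variome: Variome
) -> dict[tuple[int, str], frozenset[int]]:
    """Carrier sets: (position, valid symbol) -> sample indices carrying it."""
    mat = group.matrix()
    carriers: dict[tuple[int, str], frozenset[int]] = {}
    for pos in variome.sites:
        column = mat[:, pos - 1]
        for sym in variome.states_at(pos):
            idx = np.nonzero(column == sym.encode())[0]
            carriers[(pos, sym)] = frozenset(int(k) for k in idx)
    return carriers


def build_pair_table(
    group: AlignedGroup,
    variome: Variome,
    variant_only: bool = True,
    min_carriers: int = 1,
    store_entries: bool = True,
) -> COPairTable:
    """Score all co-observed state pairs over variome sites; flag perfect pairs.

    A genome with a missing (non-ACGT) symbol at i or j contributes to
    neither the pair count nor the single-state counts; the denominator M
    stays the full sample count. ``variant_only`` restricts perfect pairs
    to non-consensus states at both positions (the default network is a
    graph of co-occurring mutations); ``min_carriers`` discards perfect
    pairs supported by fewer carrier genomes.
    """
    carriers = state_carriers(group, variome)

    entries: dict[StatePair, tuple[int, int, int, float]] = {}
    if store_entries:
        sites = variome.sites
        states = {pos: sorted(variome.states_at(pos)) for pos in sites}
        for a in range(len(sites)):
            i = sites[a]
            for b in range(a + 1, len(sites)):
                j = sites[b]
                for x in states[i]:
                    A = carriers[(i, x)]
                    for y in states[j]:
                        B = carriers[(j, y)]
                        pc = len(A & B)
                        if pc == 0:
                            continue
                        score = pc * pc / (len(A) * len(B))
                        entries[(i, x, j, y)] = (pc, len(A), len(B), score)

    # Perfect pairs via carrier-set identity: CO = 1 iff identical carriers.
    by_carrier: dict[frozenset[int], list[tuple[int, str]]] = defaultdict(list)
    for (pos, sym), cset in carriers.items():
        if variant_only and sym == variome.consensus[pos]:
            continue
        if len(cset) < min_carriers:
            continue
        by_carrier[cset].append((pos, sym))
    perfect: set[StatePair] = set()
    for cset, members in by_carrier.items():
        members.sort()
        for (i, x), (j, y) in combinations(members, 2):
            if i != j:
                perfect.add((i, x, j, y))

    return COPairTable(
        group=group.name,
        M=group.M,
        entries=entries,
        perfect_pairs=perfect,
        carriers=carriers,
        variant_only=variant_only,
        min_carriers=min_carriers,
    )


@dataclass
class GenomeNetwork:
    """One genome's labeled co-occurrence network.

    Nodes are genome positions participating in at least one edge; node
    attributes carry the codon label and segment assignment.
    """

    group: str
    sample_id: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        return 2 * self.n_edges / self.n_nodes if self.n_nodes else 0.0


def build_genome_networks(
    group: AlignedGroup,
    table: COPairTable,
    labeling: CodonLabeling | None = None,
    collapse_trna: bool = True,
) -> list[GenomeNetwork]:
    """One network per genome: edges are the perfect pairs whose states the genome carries.

    Because a perfect pair's two states share one carrier set, a genome
    either carries both states (edge present) or neither. Genomes carrying
    no perfect-pair state get an empty network.
    """
    graphs = [nx.Graph() for _ in range(group.M)]
    for (i, x, j, y) in table.perfect_pairs:
        for g in table.carriers[(i, x)]:
            graphs[g].add_edge(i, j)
    networks = []
    for sid, G in zip(group.sample_ids, graphs):
        if labeling is not None:
            for node in G.nodes:
                G.nodes[node]["label"] = labeling.label(node)
                G.nodes[node]["segment"] = labeling.segment(
                    node, collapse_trna=collapse_trna
                )
                G.nodes[node]["segment_kind"] = labeling.segment_kind(node)
        networks.append(GenomeNetwork(group=group.name, sample_id=sid, graph=G))
    return networks


def group_network_summary(networks: list[GenomeNetwork]) -> dict[str, float]:
    """Per-group network statistics: mean/sd node and edge counts, group mean degree.

    The group mean degree is 2<E>/<N_Co> over all M networks.
    """
    n = np.array([nw.n_nodes for nw in networks], dtype=float)
    e = np.array([nw.n_edges for nw in networks], dtype=float)
    mean_n, mean_e = float(n.mean()), float(e.mean())
    return {
        "n_networks": len(networks),
        "n_co_mean": mean_n,
        "n_co_sd": float(n.std(ddof=0)),
        "e_mean": mean_e,
        "e_sd": float(e.std(ddof=0)),
        "k_mean": 2 * mean_e / mean_n if mean_n else 0.0,
    }


def copair_segment_matrix(
    networks: list[GenomeNetwork], level: str = "kind"
) -> pd.DataFrame:
    """Mean (+/- sd) edge counts per unordered segment pair over a group's networks.

    ``level="kind"`` pools segments into CDS / tRNA / rRNA / D-Loop / ORIL /
    Misc; ``level="gene"`` keeps gene names (tRNAs collapsed as stored on the
    nodes). Intra-gene vs inter-gene pairs are flagged.
    """
    if level not in {"kind", "gene"}:
        raise ValueError("level must be 'kind' or 'gene'")
    attr = "segment_kind" if level == "kind" else "segment"
    per_network: list[Counter[tuple[str, str]]] = []
    for nw in networks:
        c: Counter[tuple[str, str]] = Counter()
        for u, v in nw.graph.edges:
            a = nw.graph.nodes[u][attr]
            b = nw.graph.nodes[v][attr]
            c[tuple(sorted((a, b)))] += 1
        per_network.append(c)
    keys = sorted(set().union(*per_network)) if per_network else []
    rows = []
    for key in keys:
        counts = np.array([c.get(key, 0) for c in per_network], dtype=float)
        rows.append(
            {
                "segment_a": key[0],
                "segment_b": key[1],
                "mean": float(counts.mean()),
                "sd": float(counts.std(ddof=0)),
                "intra": key[0] == key[1],
            }
        )
    return pd.DataFrame(
        rows, columns=["segment_a", "segment_b", "mean", "sd", "intra"]
    )


def predominant_pairs(
    networks_by_group: dict[str, list[GenomeNetwork]],
    labeling: CodonLabeling | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank position pairs present as edges in >= 2 groups by total genome support.

    Ties break by ascending (i, j). Codon labels annotate each endpoint when
    a labeling is given.
    """
    if len(networks_by_group) < 2:
        raise ValueError("predominant pairs require at least two groups")
    genome_counts: dict[tuple[int, int], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for gname, networks in networks_by_group.items():
        for nw in networks:
            for u, v in nw.graph.edges:
                genome_counts[tuple(sorted((u, v)))][gname] += 1
    rows = []
    for (i, j), per_group in genome_counts.items():
        if len(per_group) < 2:
            continue
        rows.append(
            {
                "i": i,
                "j": j,
                "groups": ",".join(sorted(per_group)),
                "n_groups": len(per_group),
                "genome_count": sum(per_group.values()),
                "label_i": labeling.label(i) if labeling else None,
                "label_j": labeling.label(j) if labeling else None,
                "segment_i": labeling.segment(i, collapse_trna=True)
                if labeling
                else None,
                "segment_j": labeling.segment(j, collapse_trna=True)
                if labeling
                else None,
            }
        )
    rows.sort(key=lambda r: (-r["genome_count"], r["i"], r["j"]))
    return pd.DataFrame(
        rows[:top_n],
        columns=[
            "i",
            "j",
            "groups",
            "n_groups",
            "genome_count",
            "label_i",
            "label_j",
            "segment_i",
            "segment_j",
        ],
    )


def write_pair_table(table: COPairTable, path: str | Path) -> None:
    """Pair-table TSV: i, x, j, y, N(xy), N(x), N(y), CO, perfect flag."""
    rows = [
        {
            "i": i,
            "x": x,
            "j": j,
            "y": y,
            "pair_count": pc,
            "count_x": cx,
            "count_y": cy,
            "co": score,
            "perfect": (i, x, j, y) in table.perfect_pairs,
        }
        for (i, x, j, y), (pc, cx, cy, score) in sorted(table.entries.items())
    ]
    pd.DataFrame(
        rows,
        columns=["i", "x", "j", "y", "pair_count", "count_x", "count_y", "co", "perfect"],
    ).to_csv(path, sep="\t", index=False)


def write_network_edges(nw: GenomeNetwork, path: str | Path) -> None:
    """Edge-list TSV for one genome: i, j, labels and segments of both endpoints."""
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in nw.graph.edges):
        nu, nv = nw.graph.nodes[u], nw.graph.nodes[v]
        rows.append(
            {
                "i": u,
                "j": v,
                "label_i": nu.get("label"),
                "label_j": nv.get("label"),
                "segment_i": nu.get("segment"),
                "segment_j": nv.get("segment"),
            }
        )
    pd.DataFrame(
        rows, columns=["i", "j", "label_i", "label_j", "segment_i", "segment_j"]
    ).to_csv(path, sep="\t", index=False)
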