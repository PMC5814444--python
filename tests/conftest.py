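"""Shared fixtures and independent oracles.

The oracles re-derive quantities by brute force (per-sequence indexing,
exhaustive pair/triple scans) and stay independent of the code paths
they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from conet_mito.alignment_io import AlignedGroup

VALID = set("ACGT")


def brute_force_pair_scan(group: AlignedGroup, positions=None):
    """Exhaustive CO computation by per-sample loops.

    Returns (entries, perfect) where entries maps (i, x, j, y) ->
    (pair_count, count_x, count_y, score) for every co-observed valid
    state pair over every position pair, and perfect is the subset with
    identical carrier sets (no filters).
    """
    if positions is None:
        positions = range(1, group.L + 1)
    positions = list(positions)
    carriers: dict[tuple[int, str], set[int]] = {}
    for i in positions:
        for s, sym in enumerate(group.column(i)):
            if sym in VALID:
                carriers.setdefault((i, sym), set()).add(s)
    entries = {}
    perfect = set()
    for i, j in combinations(positions, 2):
        for (pi, x), A in carriers.items():
            if pi != i:
                continue
            for (pj, y), B in carriers.items():
                if pj != j:
                    continue
                pc = len(A & B)
                if pc == 0:
                    continue
                score = pc * pc / (len(A) * len(B))
                entries[(i, x, j, y)] = (pc, len(A), len(B), score)
                if A == B:
                    perfect.add((i, x, j, y))
    return entries, perfect


def brute_force_triangles(graph):
    """All C(n, 3) node triples with all three edges present."""
    nodes = list(graph.nodes)
    return {
        tuple(sorted((a, b, c)))
        for a, b, c in combinations(nodes, 3)
        if graph.has_edge(a, b) and graph.has_edge(b, c) and graph.has_edge(a, c)
    }


def random_group(rng: np.random.Generator, M: int, L: int, name="toy", missing=0.0):
    """A random aligned group with independent uniform columns."""
    mat = rng.integers(0, 4, size=(M, L))
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[row]) for row in mat]
    if missing > 0:
        chars = [list(s) for s in seqs]
        mask = rng.random((M, L)) < missing
        for a in range(M):
            for b in range(L):
                if mask[a, b]:
                    chars[a][b] = "N"
        seqs = ["".join(c) for c in chars]
    return AlignedGroup(
        name=name, sample_ids=[f"s{k}" for k in range(M)], sequences=seqs
    )


@pytest.fixture
def pair_scan_oracle():
    return brute_force_pair_scan


@pytest.fixture
def triangle_oracle():
    return brute_force_triangles


@pytest.fixture
def make_random_group():
    return random_group


@pytest.fixture
def toy_group():
    """Four genomes, eight columns; columns 2 and 5 share carriers {2, 3}."""
    seqs = [
        "AACGTACG",
        "AACGTACG",
        "AGCGTTCG",
        "AGCGTTCG",
    ]
    return AlignedGroup(
        name="toy", sample_ids=["a", "b", "c", "d"], sequences=seqs
    )
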