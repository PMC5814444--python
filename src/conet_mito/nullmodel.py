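"""Erdős–Rényi null ensembles matched to a group's network statistics.

Random graphs G(N, p) with p = <k>/N are generated with N equal to the
rounded group-mean node count and <k> the group mean degree, the formula
used deliberately even though the mean degree of G(N, p) is p(N-1); the
~1/N bias this introduces is documented rather than corrected. Node
codon labels are drawn i.i.d. from the group's pooled empirical
node-label distribution per realization (alternatively a fixed
representative label multiset is permuted). Motif counts of the real
networks are compared with the ensemble by empirical one-sided tail
probabilities with the add-one (R + 1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cooccurrence import GenomeNetwork
from .motifs import MotifCensus, census, group_census

LABEL_MODES = ("pooled", "fixed_multiset")


def er_realization(
    N: int,
    p: float,
    labels: Sequence[int],
    rng: np.random.Generator,
) -> nx.Graph:
    """One G(N, p) draw on N labeled nodes.

    Each of the C(N, 2) node pairs is an edge independently with
    probability p; node i carries ``labels[i]``. Deterministic given the
    generator state.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"edge probability p={p} outside [0, 1]")
    if len(labels) != N:
        raise ValueError(f"need {N} labels, got {len(labels)}")
    G = nx.Graph()
    G.add_nodes_from((i, {"label": int(labels[i])}) for i in range(N))
    iu, ju = np.triu_indices(N, k=1)
    hit = rng.random(len(iu)) < p
    G.add_edges_from(zip(iu[hit].tolist(), ju[hit].tolist()))
    return G


@dataclass
class RandomEnsemble:
    """R labeled ER realizations matched to one genome group."""

    group: str
    N: int
    k_avg: float
    p: float
    R: int
    seed: int
    label_mode: str
    censuses: list[MotifCensus]

    def null_table(self) -> pd.DataFrame:
        return group_census(self.censuses)


def empirical_label_pool(networks: list[GenomeNetwork]) -> list[int]:
    """Pooled node codon labels over all of a group's networks (with multiplicity)."""
    pool = [
        int(nw.graph.nodes[n].get("label", 0))
        for nw in networks
        for n in nw.graph.nodes
    ]
    return pool or [0]


def build_ensemble(
    n_co_mean: float,
    k_mean: float,
    label_pool: Sequence[int],
    R: int,
    seed: int,
    group: str = "null",
    label_mode: str = "pooled",
) -> RandomEnsemble:
    """R labeled G(N, p) realizations with N = round(<N_Co>), p = <k>/N."""
    if label_mode not in LABEL_MODES:
        raise ValueError(f"label_mode must be one of {LABEL_MODES}")
    N = int(round(n_co_mean))
    if N < 2:
        raise ValueError(f"ensemble needs N >= 2 nodes, got {N}")
    if R < 1:
        raise ValueError("R must be >= 1")
    p = k_mean / N
    if not 0 <= p <= 1:
        raise ValueError(f"p = k/N = {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    pool = np.asarray(label_pool, dtype=int)
    fixed = None
    if label_mode == "fixed_multiset":
        # one representative multiset of size N, reused (permuted) each draw
        fixed = pool[rng.integers(0, len(pool), size=N)]
    censuses: list[MotifCensus] = []
    for r in range(R):
        if label_mode == "pooled":
            labels = pool[rng.integers(0, len(pool), size=N)]
        else:
            labels = rng.permutation(fixed)
        G = er_realization(N, p, labels, rng)
        nw = GenomeNetwork(group=group, sample_id=f"er_{r}", graph=G)
        censuses.append(census(nw))
    return RandomEnsemble(
        group=group,
        N=N,
        k_avg=k_mean,
        p=p,
        R=R,
        seed=seed,
        label_mode=label_mode,
        censuses=censuses,
    )


def compare(real_table: pd.DataFrame, ensemble: RandomEnsemble) -> pd.DataFrame:
    """Per-type enrichment of real motif counts against the null ensemble.

    For each motif type, the empirical one-sided tail probability is
    (b + 1) / (R + 1) where b is the number of realizations whose count
    is at least the real per-network mean; a z-score is reported whenever
    the null sd is positive.
    """
    R = ensemble.R
    null_counts = {
        ("TNM", 2): [c.tnm_counts for c in ensemble.censuses],
        ("ThNM", 3): [c.thnm_counts for c in ensemble.censuses],
    }
    rows = []
    for _, row in real_table.iterrows():
        scope = row["scope"]
        counters = null_counts[(scope, 2 if scope == "TNM" else 3)]
        counts = np.array([c.get(row["type"], 0) for c in counters], dtype=float)
        real_mean = float(row["mean"])
        null_mean = float(counts.mean())
        null_sd = float(counts.std(ddof=0))
        b = int((counts >= real_mean).sum())
        rows.append(
            {
                "type": row["type"],
                "scope": scope,
                "real_mean": real_mean,
                "null_mean": null_mean,
                "null_sd": null_sd,
                "z": (real_mean - null_mean) / null_sd if null_sd > 0 else np.nan,
                "tail_p": (b + 1) / (R + 1),
                "R": R,
                "seed": ensemble.seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "type",
            "scope",
            "real_mean",
            "null_mean",
            "null_sd",
            "z",
            "tail_p",
            "R",
            "seed",
        ],
    )
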