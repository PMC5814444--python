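"""Variable-site extraction and cross-group variome comparison.

A group's variome is the set of alignment columns carrying at least two
distinct valid nucleotide states among the group's samples. Non-ACGT
symbols (ambiguity codes, gaps, N) are missing data and never create
variability on their own; a config switch restores gap-as-allele
behaviour for alignments where indels are informative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .alignment_io import AlignedGroup
from .annotation import CodonLabeling

_SYMBOL_ORDER = {b"A": 0, b"C": 1, b"G": 2, b"T": 3, b"-": 4}


class CoordinateError(ValueError):
    """Groups being compared do not share one alignment coordinate system."""


@dataclass
class Variome:
    """Variable sites of one group with consensus and per-state carrier counts."""

    group: str
    sites: list[int]
    consensus: dict[int, str]
    state_counts: dict[tuple[int, str], int]
    M: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def states_at(self, i: int) -> dict[str, int]:
        return {
            sym: n for (pos, sym), n in self.state_counts.items() if pos == i
        }


def extract_variome(
    group: AlignedGroup, count_gaps_as_state: bool = False
) -> Variome:
    """Identify columns with >=2 distinct valid states; record consensus and counts.

    Consensus is the modal valid symbol, ties broken by fixed symbol order
    A < C < G < T (< -). With ``count_gaps_as_state`` the gap character is a
    fifth allele; otherwise it is missing data.
    """
    valid = [b"A", b"C", b"G", b"T"] + ([b"-"] if count_gaps_as_state else [])
    mat = group.matrix()
    sites: list[int] = []
    consensus: dict[int, str] = {}
    state_counts: dict[tuple[int, str], int] = {}
    for col in range(group.L):
        column = mat[:, col]
        counts = [(sym, int((column == sym).sum())) for sym in valid]
        counts = [(s, n) for s, n in counts if n > 0]
        if len(counts) < 2:
            continue
        pos = col + 1
        sites.append(pos)
        # max count, ties by symbol order
        best = min(counts, key=lambda t: (-t[1], _SYMBOL_ORDER[t[0]]))
        consensus[pos] = best[0].decode()
        for sym, n in counts:
            state_counts[(pos, sym.decode())] = n
    return Variome(
        group=group.name,
        sites=sites,
        consensus=consensus,
        state_counts=state_counts,
        M=group.M,
    )


def variome_overlap(variomes: list[Variome]) -> dict[frozenset[str], int]:
    """Exact Venn partition of variable sites over groups.

    For every nonempty subset of group names, the number of positions whose
    group membership is exactly that subset. Counts over all subsets sum to
    the size of the union of the site sets.
    """
    if len(variomes) < 2:
        raise ValueError("need at least two variomes to compare")
    names = [v.group for v in variomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names among variomes")
    site_sets = {v.group: set(v.sites) for v in variomes}
    partition: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(names) + 1)
        for sub in combinations(names, r)
    }
    for pos in set().union(*site_sets.values()):
        members = frozenset(n for n in names if pos in site_sets[n])
        partition[members] += 1
    return partition


def overlap_table(partition: dict[frozenset[str], int], names: list[str]) -> pd.DataFrame:
    """Serialize a Venn partition: bitmask, member names, count."""
    rows = []
    for subset, count in partition.items():
        mask = "".join("1" if n in subset else "0" for n in names)
        rows.append(
            {
                "bitmask": mask,
                "groups": ",".join(n for n in names if n in subset),
                "n_groups": len(subset),
                "count": count,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["n_groups", "bitmask"], ascending=[False, False]
    )
    return df.reset_index(drop=True)


def segment_tally(
    v: Variome, labeling: CodonLabeling, collapse_trna: bool = True
) -> pd.DataFrame:
    """Per-segment counts and percentages of a group's variable sites."""
    counts: Counter[str] = Counter(
        labeling.segment(i, collapse_trna=collapse_trna) for i in v.sites
    )
    total = v.n_sites
    rows = [
        {
            "segment": seg,
            "count": n,
            "percent": 100.0 * n / total if total else 0.0,
        }
        for seg, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["segment", "count", "percent"])


def write_variome(
    v: Variome, labeling: CodonLabeling, path: str | Path, collapse_trna: bool = False
) -> None:
    """Variome TSV: position, consensus, states with counts, segment, codon label.

    Positions are 1-based alignment columns.
    """
    rows = []
    for pos in v.sites:
        states = v.states_at(pos)
        rows.append(
            {
                "position": pos,
                "consensus": v.consensus[pos],
                "states": ";".join(f"{s}:{n}" for s, n in sorted(states.items())),
                "segment": labeling.segment(pos, collapse_trna=collapse_trna),
                "codon_label": labeling.label(pos),
            }
        )
    pd.DataFrame(
        rows, columns=["position", "consensus", "states", "segment", "codon_label"]
    ).to_csv(path, sep="\t", index=False)
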