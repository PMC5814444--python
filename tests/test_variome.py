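"""Variable-site extraction, Venn overlap and segment tallies."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conet_mito.alignment_io import AlignedGroup
from conet_mito.annotation import Feature, GeneAnnotation, codon_labels
from conet_mito.variome import (
    Variome,
    extract_variome,
    overlap_table,
    segment_tally,
    variome_overlap,
)


def make_group(columns, name="G"):
    """Build a group from a list of per-position symbol lists."""
    M = len(columns[0])
    seqs = ["".join(col[s] for col in columns) for s in range(M)]
    return AlignedGroup(name=name, sample_ids=[f"s{k}" for k in range(M)], sequences=seqs)


def test_identical_sequences_have_empty_variome():
    g = AlignedGroup("G", ["a", "b", "c"], ["ACGT"] * 3)
    assert extract_variome(g).sites == []


def test_variable_column_definition_and_consensus():
    g = make_group([list("AAG"), list("CCC"), list("ANA")])
    v = extract_variome(g)
    assert v.sites == [1]  # column 3 has one valid state, N is missing
    assert v.consensus[1] == "A"
    assert v.states_at(1) == {"A": 2, "G": 1}


def test_missing_symbols_never_create_variability():
    g = make_group([list("AN-A")])
    assert extract_variome(g).sites == []


def test_gap_as_state_switch():
    g = make_group([list("AA--")])
    assert extract_variome(g).sites == []
    v = extract_variome(g, count_gaps_as_state=True)
    assert v.sites == [1]
    assert v.consensus[1] == "A"  # tie broken by symbol order A < -


def test_consensus_tie_breaks_lexicographically():
    g = make_group([list("GGTT")])
    v = extract_variome(g)
    assert v.consensus[1] == "G"


def test_brute_force_column_scan_oracle(make_random_group):
    rng = np.random.default_rng(11)
    g = make_random_group(rng, M=8, L=60, missing=0.15)
    v = extract_variome(g)
    expected = []
    for i in range(1, g.L + 1):
        valid = [s for s in g.column(i) if s in set("ACGT")]
        if len(set(valid)) >= 2:
            expected.append(i)
    assert v.sites == expected


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_order_invariance_and_duplication_monotonicity(seed):
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 4, size=(5, 20))
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[row]) for row in mat]
    g = AlignedGroup("G", [f"s{k}" for k in range(5)], seqs)
    perm = rng.permutation(5)
    g_perm = AlignedGroup(
        "G", [f"s{k}" for k in perm], [seqs[k] for k in perm]
    )
    assert extract_variome(g).sites == extract_variome(g_perm).sites
    # duplicating a sequence adds no sites
    g_dup = AlignedGroup("G", [f"s{k}" for k in range(5)] + ["dup"], seqs + [seqs[0]])
    assert extract_variome(g_dup).sites == extract_variome(g).sites


def _variome(name, sites):
    return Variome(
        group=name,
        sites=sorted(sites),
        consensus={s: "A" for s in sites},
        state_counts={(s, "A"): 1 for s in sites},
        M=2,
    )


def test_overlap_identical_and_disjoint():
    a, b = _variome("A", {10, 20}), _variome("B", {10, 20})
    part = variome_overlap([a, b])
    assert part[frozenset({"A", "B"})] == 2
    assert part[frozenset({"A"})] == 0 and part[frozenset({"B"})] == 0

    c = _variome("C", {1, 2, 3})
    d = _variome("D", {4, 5, 6, 7})
    part = variome_overlap([c, d])
    assert part[frozenset({"C"})] == 3
    assert part[frozenset({"D"})] == 4
    assert part[frozenset({"C", "D"})] == 0


def test_overlap_matches_exhaustive_subset_oracle():
    rng = np.random.default_rng(3)
    names = ["A", "B", "C", "D"]
    site_sets = {n: set(rng.choice(50, size=rng.integers(5, 20), replace=False)) for n in names}
    variomes = [_variome(n, site_sets[n]) for n in names]
    part = variome_overlap(variomes)
    # oracle: exhaustive set algebra over all subsets
    union = set().union(*site_sets.values())
    for r in range(1, 5):
        for sub in combinations(names, r):
            inside = set(union)
            for n in sub:
                inside &= site_sets[n]
            for n in set(names) - set(sub):
                inside -= site_sets[n]
            assert part[frozenset(sub)] == len(inside)
    assert sum(part.values()) == len(union)


def test_overlap_table_serialization():
    a, b = _variome("A", {1, 2}), _variome("B", {2, 3})
    df = overlap_table(variome_overlap([a, b]), ["A", "B"])
    assert set(df["bitmask"]) == {"10", "01", "11"}
    assert df.loc[df.bitmask == "11", "count"].item() == 1
    assert df["count"].sum() == 3


def test_segment_tally_against_recount_oracle():
    ann = GeneAnnotation(
        [
            Feature("G1", 1, 9, "+", "CDS"),
            Feature("T1", 10, 15, "+", "tRNA"),
            Feature("T2", 16, 21, "+", "tRNA"),
        ],
        reference_length=30,
    )
    lab = codon_labels(ann)
    v = _variome("A", {2, 5, 11, 17, 25})
    df = segment_tally(v, lab, collapse_trna=True)
    tally = dict(zip(df.segment, df["count"]))
    assert tally == {"G1": 2, "tRNA": 2, "Misc": 1}
    assert df["percent"].sum() == pytest.approx(100.0)
    # all sites inside one CDS -> 100%
    v2 = _variome("A", {1, 4, 7})
    df2 = segment_tally(v2, lab)
    assert df2.segment.tolist() == ["G1"] and df2.percent.item() == 100.0


def test_empty_variome_tally_is_empty():
    ann = GeneAnnotation([], reference_length=10)
    lab = codon_labels(ann)
    df = segment_tally(_variome("A", set()), lab)
    assert len(df) == 0
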