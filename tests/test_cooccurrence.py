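"""Co-occurrence scoring, perfect-pair detection and per-genome networks."""

import numpy as np
import pytest

from conet_mito.alignment_io import AlignedGroup
from conet_mito.annotation import Feature, GeneAnnotation, codon_labels
from conet_mito.cooccurrence import (
    build_genome_networks,
    build_pair_table,
    co_occurrence_score,
    copair_segment_matrix,
    group_network_summary,
    predominant_pairs,
)
from conet_mito.variome import extract_variome


@pytest.mark.parametrize(
    "pair_count,count_x,count_y,M,expected",
    [
        (5, 5, 5, 10, 1.0),  # perfect co-segregation
        (2, 4, 4, 8, 0.25),  # independence identity: CO = f(x) f(y)
        (0, 3, 4, 10, 0.0),  # never co-observed
        (1, 1, 1, 2, 1.0),  # singleton-singleton perfection
    ],
)
def test_score_arithmetic(pair_count, count_x, count_y, M, expected):
    assert co_occurrence_score(pair_count, count_x, count_y, M) == expected


def test_score_domain_errors():
    with pytest.raises(ValueError):
        co_occurrence_score(1, 0, 2, 4)
    with pytest.raises(ValueError):
        co_occurrence_score(3, 2, 2, 4)  # pair_count > min(counts)


def test_score_bounded_unit_interval():
    rng = np.random.default_rng(0)
    for _ in range(200):
        cx, cy = rng.integers(1, 10, size=2)
        pc = rng.integers(0, min(cx, cy) + 1)
        assert 0 <= co_occurrence_score(int(pc), int(cx), int(cy), 12) <= 1


def _group(seqs, name="G"):
    return AlignedGroup(name, [f"s{k}" for k in range(len(seqs))], seqs)


def test_identical_carrier_partition_gives_perfect_pairs():
    # columns 1 and 2: carriers of G at 1 and T at 2 are both {2};
    # carriers of A at 1 and C at 2 are both {0, 1}
    g = _group(["AC", "AC", "GT"])
    v = extract_variome(g)
    table = build_pair_table(g, v, variant_only=False)
    assert (1, "G", 2, "T") in table.perfect_pairs
    assert (1, "A", 2, "C") in table.perfect_pairs
    # with the variant-only filter the consensus-consensus pair is excluded
    table_vo = build_pair_table(g, v, variant_only=True)
    assert (1, "G", 2, "T") in table_vo.perfect_pairs
    assert (1, "A", 2, "C") not in table_vo.perfect_pairs


def test_partial_overlap_is_imperfect():
    # variants at both columns carried by 2 genomes each, overlapping in 1
    g = _group(["GT", "GC", "AT", "AC"])
    v = extract_variome(g)
    table = build_pair_table(g, v, variant_only=False)
    entry = table.entries[(1, "G", 2, "T")]
    assert entry[:3] == (1, 2, 2)
    assert entry[3] == 0.25
    assert (1, "G", 2, "T") not in table.perfect_pairs


def test_min_carriers_filter():
    g = _group(["GT", "AC", "AC", "AC"])
    v = extract_variome(g)
    assert len(build_pair_table(g, v, min_carriers=1).perfect_pairs) == 1
    assert len(build_pair_table(g, v, min_carriers=2).perfect_pairs) == 0


def test_pair_table_matches_brute_force_oracle(make_random_group, pair_scan_oracle):
    rng = np.random.default_rng(23)
    g = make_random_group(rng, M=6, L=25, missing=0.1)
    v = extract_variome(g)
    table = build_pair_table(g, v, variant_only=False)
    entries, perfect = pair_scan_oracle(g, positions=v.sites)
    assert table.entries == entries
    assert table.perfect_pairs == perfect


def test_missing_symbol_blocks_perfection():
    # s0 has N at column 2: carrier of G at 1 is {0, 1} but of T at 2 only {1}
    g = _group(["GN", "GT", "AC", "AC"])
    v = extract_variome(g)
    table = build_pair_table(g, v, variant_only=False)
    assert (1, "G", 2, "T") in table.entries
    pc, cx, cy, score = table.entries[(1, "G", 2, "T")]
    assert (pc, cx, cy) == (1, 2, 1)
    assert (1, "G", 2, "T") not in table.perfect_pairs


def _toy_network_setup():
    # columns 1-4: a planted carrier set {2, 3} at columns 1, 2, 3 (triangle
    # for carriers) and an independent variant at column 4
    seqs = ["AAAA", "AAAA", "CCCA", "CCCA", "AAAT"]
    g = _group(seqs)
    ann = GeneAnnotation([Feature("G1", 1, 3, "+", "CDS")], reference_length=4)
    lab = codon_labels(ann)
    v = extract_variome(g)
    table = build_pair_table(g, v)
    networks = build_genome_networks(g, table, lab)
    return g, table, networks


def test_genome_networks_follow_carrier_states():
    g, table, networks = _toy_network_setup()
    by_id = {nw.sample_id: nw for nw in networks}
    assert len(networks) == g.M
    # carriers of the planted block get the 3-clique
    for sid in ("s2", "s3"):
        assert by_id[sid].n_edges == 3 and by_id[sid].n_nodes == 3
    # non-carriers get empty networks
    for sid in ("s0", "s1", "s4"):
        assert by_id[sid].n_edges == 0


def test_no_phantom_edges_and_union_covers_perfect_pairs():
    _, table, networks = _toy_network_setup()
    union = set()
    for nw in networks:
        for u, v_ in nw.graph.edges:
            union.add(tuple(sorted((u, v_))))
    projected = {tuple(sorted((i, j))) for (i, _, j, _) in table.perfect_pairs}
    assert union == projected


def test_group_summary_recounts():
    _, _, networks = _toy_network_setup()
    s = group_network_summary(networks)
    n = [nw.n_nodes for nw in networks]
    e = [nw.n_edges for nw in networks]
    assert s["n_co_mean"] == pytest.approx(np.mean(n))
    assert s["e_mean"] == pytest.approx(np.mean(e))
    assert s["k_mean"] == pytest.approx(2 * np.mean(e) / np.mean(n))


def test_segment_matrix_recount_oracle():
    _, _, networks = _toy_network_setup()
    df = copair_segment_matrix(networks, level="gene")
    # all edges lie inside gene G1 -> single diagonal cell
    assert df.segment_a.tolist() == ["G1"] and df.segment_b.tolist() == ["G1"]
    assert df["intra"].all()
    # mean over 5 networks: carriers s2, s3 contribute 3 edges each
    assert df["mean"].item() == pytest.approx(6 / 5)
    # single-network matrix has zero sd
    single = copair_segment_matrix(networks[2:3], level="gene")
    assert (single["sd"] == 0).all()


def test_predominant_pairs_ranking():
    seqs_a = ["GT", "GT", "AC", "AC", "AC"]
    seqs_b = ["GT", "GT", "GT", "AC", "AC"]
    ga, gb = _group(seqs_a, "A"), _group(seqs_b, "B")
    nets = {}
    for g in (ga, gb):
        v = extract_variome(g)
        table = build_pair_table(g, v)
        nets[g.name] = build_genome_networks(g, table)
    df = predominant_pairs(nets, top_n=10)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.i, row.j) == (1, 2)
    # A: minor states G/T carried by 2 genomes; B: G/T is the majority there,
    # so the minor pair A/C (2 carriers) forms the edge
    assert row.genome_count == 4
    assert row.n_groups == 2


def test_predominant_pairs_excludes_single_group_and_requires_two_groups():
    g = _group(["GT", "GT", "AC", "AC"])
    v = extract_variome(g)
    table = build_pair_table(g, v)
    nets = build_genome_networks(g, table)
    with pytest.raises(ValueError):
        predominant_pairs({"A": nets})
    # pair present in one group only is excluded
    g2 = _group(["AA", "AA", "AC", "CA"], "B")
    nets2 = build_genome_networks(
        g2, build_pair_table(g2, extract_variome(g2))
    )
    df = predominant_pairs({"A": nets, "B": nets2})
    assert len(df) == 0
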