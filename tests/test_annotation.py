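"""Feature maps, codon-frame labeling and segment assignment."""

from collections import Counter

import pytest

from conet_mito.annotation import (
    AnnotationParseError,
    ConfigurationError,
    Feature,
    GeneAnnotation,
    codon_labels,
    load_annotation,
    load_rcrs,
    segment_of,
    write_annotation,
)


def test_rcrs_fixture_feature_counts():
    ann = load_rcrs()
    counts = ann.count_by_kind()
    assert counts["CDS"] == 13
    assert counts["tRNA"] == 22
    assert counts["rRNA"] == 2
    assert ann.reference_length == 16569


def test_empty_table_labels_everything_zero(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("# reference_length=30\n")
    ann = load_annotation(p)
    assert ann.features == []
    lab = codon_labels(ann)
    assert all(lab.label(i) == 0 for i in range(1, 31))
    assert all(lab.segment(i) == "Misc" for i in range(1, 31))


def test_annotation_round_trip(tmp_path):
    ann = GeneAnnotation(
        features=[
            Feature("G1", 11, 19, "+", "CDS"),
            Feature("T1", 25, 40, "+", "tRNA"),
            Feature("G2", 50, 60, "-", "CDS", incomplete_stop=True),
        ],
        reference_length=80,
    )
    path = tmp_path / "ann.tsv"
    write_annotation(ann, path)
    ann2 = load_annotation(path)
    assert ann2.reference_length == 80
    assert [
        (f.name, f.start, f.end, f.strand, f.kind, f.incomplete_stop)
        for f in ann2.features
    ] == [
        (f.name, f.start, f.end, f.strand, f.kind, f.incomplete_stop)
        for f in ann.features
    ]


def test_malformed_row_reports_line_number(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("G1\t11\t19\t+\tCDS\t.\nG2\tnotanint\t20\t+\tCDS\t.\n")
    with pytest.raises(AnnotationParseError, match=":2:"):
        load_annotation(p)


def test_plus_strand_frame():
    ann = GeneAnnotation([Feature("G", 11, 19, "+", "CDS")], reference_length=30)
    lab = codon_labels(ann)
    assert [lab.label(i) for i in range(11, 20)] == [1, 2, 3, 1, 2, 3, 1, 2, 3]
    assert lab.label(10) == 0 and lab.label(20) == 0


def test_minus_strand_frame_mirror_oracle():
    """Minus-strand labels equal plus-strand labels read along the reversed axis."""
    ann_minus = GeneAnnotation([Feature("G", 11, 19, "-", "CDS")], reference_length=30)
    lab_minus = codon_labels(ann_minus)
    # oracle: label position 19 as 1, walking 19 -> 11
    expected = {19 - k: k % 3 + 1 for k in range(9)}
    assert {i: lab_minus.label(i) for i in range(11, 20)} == expected
    assert lab_minus.label(11) == 3


def test_strand_symmetry_property():
    """Reversing strand and coordinate axis yields the same label sequence."""
    L = 60
    plus = codon_labels(
        GeneAnnotation([Feature("G", 21, 38, "+", "CDS")], reference_length=L)
    )
    minus = codon_labels(
        GeneAnnotation(
            [Feature("G", L - 38 + 1, L - 21 + 1, "-", "CDS")], reference_length=L
        )
    )
    fwd = [plus.label(i) for i in range(21, 39)]
    rev = [minus.label(L - i + 1) for i in range(21, 39)]
    assert fwd == rev


def test_cds_label_histogram_balanced():
    ann = GeneAnnotation([Feature("G", 100, 100 + 3 * 7 - 1, "+", "CDS")], 300)
    lab = codon_labels(ann)
    hist = Counter(lab.label(i) for i in range(100, 121))
    assert hist == {1: 7, 2: 7, 3: 7}


def test_trna_position_label_zero_segment_collapse():
    ann = GeneAnnotation([Feature("TRNF", 5, 20, "+", "tRNA")], reference_length=30)
    lab = codon_labels(ann)
    assert lab.label(10) == 0
    assert segment_of(lab, 10) == "TRNF"
    assert segment_of(lab, 10, collapse_trna=True) == "tRNA"
    assert segment_of(lab, 25) == "Misc"


def test_overlapping_cds_first_start_wins_and_conflicts_reported():
    ann = GeneAnnotation(
        [
            Feature("A", 1, 12, "+", "CDS"),
            Feature("B", 11, 22, "+", "CDS"),
        ],
        reference_length=30,
    )
    lab = codon_labels(ann)
    # positions 11, 12 belong to A (starts first); A's frame continues
    assert lab.segment(11) == "A" and lab.segment(12) == "A"
    assert lab.label(11) == 2 and lab.label(12) == 3
    # B's frame disagrees with A's at both shared positions
    conflict_positions = {pos for pos, _, _ in lab.frame_conflicts}
    assert conflict_positions == {11, 12}


def test_labeling_is_total_and_idempotent():
    ann = load_rcrs()
    lab1 = codon_labels(ann)
    lab2 = codon_labels(ann)
    assert (lab1.labels == lab2.labels).all()
    assert set(lab1.labels[1:]) <= {0, 1, 2, 3}
    assert all(lab1.segment_kinds[i] is not None for i in range(1, ann.reference_length + 1))


def test_projection_required_and_applied():
    ann = GeneAnnotation([Feature("G", 1, 9, "+", "CDS")], reference_length=9)
    with pytest.raises(ConfigurationError):
        codon_labels(ann, alignment_length=11)
    # alignment has an insertion column at 5
    projection = {c: (c if c < 5 else (None if c == 5 else c - 1)) for c in range(1, 11)}
    lab = codon_labels(ann, alignment_length=10, projection=projection)
    assert lab.label(4) == 1  # ref position 4
    assert lab.label(5) == 0 and lab.segment(5) == "Misc"  # insertion column
    assert lab.label(6) == 2  # ref position 5


def test_incomplete_stop_continues_cycle():
    ann = GeneAnnotation(
        [Feature("G", 1, 10, "+", "CDS", incomplete_stop=True)], reference_length=12
    )
    lab = codon_labels(ann)
    assert lab.label(10) == 1  # cycle continues past the last full codon


def test_gff3_fixture_agrees_with_tsv_fixture():
    from importlib import resources

    ref = resources.files("conet_mito.data") / "rcrs_features.gff3"
    with resources.as_file(ref) as path:
        ann = load_annotation(path)
    assert ann.reference_length == 16569
    assert ann.count_by_kind() == load_rcrs().count_by_kind()
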