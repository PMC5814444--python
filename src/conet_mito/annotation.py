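"""Reference feature maps and codon-position labeling.

Every genome position receives a codon label — 1, 2 or 3 inside a
protein-coding gene according to that gene's own reading frame, 0
everywhere else — and a genomic-segment assignment (gene name plus a
feature kind: CDS, tRNA, rRNA, D-Loop, ORIL or Misc). A packaged feature
table for the human mtDNA reference (rCRS, NC_012920) ships with the
package.

Conventions for situations the label definition leaves open:

* Overlapping CDS (ATP8/ATP6, ND4L/ND4 in rCRS): the feature that starts
  first labels the shared positions; conflicting-frame positions are
  recorded in :attr:`CodonLabeling.frame_conflicts`.
* Minus-strand CDS (ND6) are labeled along their own reading direction:
  the 3'-most reference coordinate of the gene is codon position 1.
* Incomplete terminal codons (polyadenylation-completed stops) continue
  the 1,2,3 cycle to the gene end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

KINDS = ("CDS", "tRNA", "rRNA", "D-Loop", "ORIL", "Misc")
_KIND_ALIASES = {
    "DLoop": "D-Loop",
    "D_loop": "D-Loop",
    "d-loop": "D-Loop",
    "OriL": "ORIL",
    "rep_origin": "ORIL",
}
_GFF_TYPE_TO_KIND = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D_loop": "D-Loop",
    "rep_origin": "ORIL",
}


class AnnotationParseError(ValueError):
    """Malformed feature-table row (message carries the line number)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent coordinate-projection configuration."""


@dataclass(frozen=True)
class Feature:
    name: str
    start: int
    end: int
    strand: str
    kind: str
    incomplete_stop: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"feature {self.name}: bad span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: strand must be + or -")
        if self.kind not in KINDS:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """A validated reference feature map."""

    features: list[Feature]
    reference_length: int

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > self.reference_length:
                raise ValueError(
                    f"feature {f.name} ends at {f.end} beyond reference length "
                    f"{self.reference_length}"
                )
            if f.kind == "CDS" and f.length % 3 != 0 and not f.incomplete_stop:
                raise ValueError(
                    f"CDS {f.name} has length {f.length} not divisible by 3 and "
                    "no incomplete_stop flag"
                )

    def count_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out


@dataclass
class CodonLabeling:
    """Total per-position codon labels and segment assignments.

    ``labels[i]`` and the segment arrays are indexed by 1-based position;
    index 0 is unused padding.
    """

    labels: np.ndarray
    segment_names: np.ndarray
    segment_kinds: np.ndarray
    frame_conflicts: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.labels) - 1

    def label(self, i: int) -> int:
        self._check(i)
        return int(self.labels[i])

    def segment(self, i: int, collapse_trna: bool = False) -> str:
        self._check(i)
        if collapse_trna and self.segment_kinds[i] == "tRNA":
            return "tRNA"
        return str(self.segment_names[i])

    def segment_kind(self, i: int) -> str:
        self._check(i)
        return str(self.segment_kinds[i])

    def _check(self, i: int) -> None:
        if not 1 <= i <= self.L:
            raise IndexError(f"position {i} out of range 1..{self.L}")


def _kind_from_token(token: str) -> str:
    token = token.strip()
    if token in KINDS:
        return token
    if token in _KIND_ALIASES:
        return _KIND_ALIASES[token]
    raise ValueError(f"unknown feature kind {token!r}")


def load_annotation(
    table_path: str | Path, reference_length: int | None = None
) -> GeneAnnotation:
    """Load a feature map from a 6-column TSV or a GFF3 file.

    TSV columns: name, start, end, strand, kind, notes. A note containing
    ``incomplete_stop`` marks CDS with polyadenylation-completed stop codons.
    ``reference_length`` defaults to a ``# reference_length=N`` header
    directive if present, else to the largest feature end.
    """
    table_path = Path(table_path)
    text = table_path.read_text()
    if table_path.suffix in {".gff", ".gff3"} or text.startswith("##gff"):
        features = _parse_gff3(text, table_path)
    else:
        features = _parse_tsv(text, table_path)
    if reference_length is None:
        for line in text.splitlines():
            stripped = line.lstrip("# ").strip()
            if stripped.startswith("reference_length="):
                reference_length = int(stripped.split("=", 1)[1])
                break
            if stripped.startswith("sequence-region"):
                reference_length = int(stripped.split()[-1])
                break
    if reference_length is None:
        reference_length = max((f.end for f in features), default=0)
    _warn_duplicates(features)
    return GeneAnnotation(features=features, reference_length=reference_length)


def _parse_tsv(text: str, path: Path) -> list[Feature]:
    features: list[Feature] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise AnnotationParseError(
                f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(parts)}"
            )
        name, start, end, strand, kind = parts[:5]
        notes = parts[5] if len(parts) > 5 else ""
        try:
            feat = Feature(
                name=name,
                start=int(start),
                end=int(end),
                strand=strand,
                kind=_kind_from_token(kind),
                incomplete_stop="incomplete_stop" in notes,
                notes=notes,
            )
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
        features.append(feat)
    return features


def _parse_gff3(text: str, path: Path) -> list[Feature]:
    features: list[Feature] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise AnnotationParseError(
                f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}"
            )
        _, _, ftype, start, end, _, strand, _, attrs = parts
        if ftype not in _GFF_TYPE_TO_KIND:
            continue  # gene/exon/region wrappers around typed records
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = attr_map.get("Name") or attr_map.get("gene") or attr_map.get("ID", "?")
        try:
            feat = Feature(
                name=name,
                start=int(start),
                end=int(end),
                strand=strand if strand in "+-" else "+",
                kind=_GFF_TYPE_TO_KIND[ftype],
                incomplete_stop="incomplete_stop" in attrs,
                notes=attr_map.get("Note", ""),
            )
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
        features.append(feat)
    return features


def _warn_duplicates(features: list[Feature]) -> None:
    seen: dict[tuple[str, int, int, str], int] = {}
    for f in features:
        key = (f.name, f.start, f.end, f.kind)
        seen[key] = seen.get(key, 0) + 1
    for key, n in seen.items():
        if n > 1:
            warnings.warn(f"duplicate feature record {key[0]} {key[1]}..{key[2]}")


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write the 6-column TSV form (inverse of :func:`load_annotation`)."""
    lines = [
        f"# reference_length={ann.reference_length}",
        "# name\tstart\tend\tstrand\tkind\tnotes",
    ]
    for f in ann.features:
        notes = f.notes
        if f.incomplete_stop and "incomplete_stop" not in notes:
            notes = (notes + " incomplete_stop").strip()
        lines.append(f"{f.name}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\t{notes or '.'}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_rcrs() -> GeneAnnotation:
    """The packaged rCRS (NC_012920) feature map: 13 CDS, 22 tRNA, 2 rRNA,
    the split control region, and the light-strand origin."""
    ref = resources.files("conet_mito.data") / "rcrs_features.tsv"
    with resources.as_file(ref) as path:
        return load_annotation(path, reference_length=16569)


def read_projection(path: str | Path) -> dict[int, int | None]:
    """Read a 2-column projection table: alignment column -> reference position or '-'."""
    out: dict[int, int | None] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        col, ref = line.split("\t")[:2]
        out[int(col)] = None if ref == "-" else int(ref)
    return out


def codon_labels(
    ann: GeneAnnotation,
    alignment_length: int | None = None,
    projection: dict[int, int | None] | None = None,
) -> CodonLabeling:
    """Assign every position a codon label (1/2/3 in CDS frame, else 0) and a segment.

    When the alignment length differs from the reference length a projection
    (alignment column -> reference position, ``None`` for insertion columns)
    is required; insertion columns get label 0, segment Misc.
    """
    L_ref = ann.reference_length
    ref_labels = np.zeros(L_ref + 1, dtype=np.int8)
    ref_names = np.full(L_ref + 1, "Misc", dtype=object)
    ref_kinds = np.full(L_ref + 1, "Misc", dtype=object)
    assigned = np.zeros(L_ref + 1, dtype=bool)
    conflicts: list[tuple[int, int, int]] = []

    ordered = sorted(enumerate(ann.features), key=lambda t: (t[1].start, t[0]))
    for _, f in ordered:
        for pos in range(f.start, f.end + 1):
            lab = _frame_label(f, pos) if f.kind == "CDS" else 0
            if not assigned[pos]:
                assigned[pos] = True
                ref_names[pos] = f.name
                ref_kinds[pos] = f.kind
                ref_labels[pos] = lab
            elif f.kind == "CDS" and ref_kinds[pos] == "CDS" and lab != ref_labels[pos]:
                conflicts.append((pos, int(ref_labels[pos]), lab))

    if alignment_length is None or alignment_length == L_ref:
        return CodonLabeling(ref_labels, ref_names, ref_kinds, conflicts)

    if projection is None:
        raise ConfigurationError(
            f"alignment length {alignment_length} differs from reference length "
            f"{L_ref}; a projection table is required"
        )
    labels = np.zeros(alignment_length + 1, dtype=np.int8)
    names = np.full(alignment_length + 1, "Misc", dtype=object)
    kinds = np.full(alignment_length + 1, "Misc", dtype=object)
    for col in range(1, alignment_length + 1):
        ref = projection.get(col)
        if ref is not None and 1 <= ref <= L_ref:
            labels[col] = ref_labels[ref]
            names[col] = ref_names[ref]
            kinds[col] = ref_kinds[ref]
    return CodonLabeling(labels, names, kinds, conflicts)


def _frame_label(f: Feature, pos: int) -> int:
    """Codon position of ``pos`` within CDS ``f`` along its reading direction."""
    if f.strand == "+":
        return (pos - f.start) % 3 + 1
    return (f.end - pos) % 3 + 1


def segment_of(labeling: CodonLabeling, i: int, collapse_trna: bool = False) -> str:
    """Segment name at position ``i``; optionally collapse all tRNA genes to 'tRNA'."""
    return labeling.segment(i, collapse_trna=collapse_trna)
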