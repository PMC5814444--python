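"""Reading, validating and indexing groups of end-to-end aligned genomes.

Sequences arrive pre-aligned over one shared coordinate system; positions
are 1-based inclusive alignment columns throughout the package. Symbols
outside {A, C, G, T} (IUPAC ambiguity codes, ``N``, gaps ``-``) are retained
on read but treated as missing by downstream frequency counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_SYMBOLS = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised when a record set violates the aligned-group invariants."""


class InputError(ValueError):
    """Raised on empty or malformed input files."""


@dataclass
class AlignedGroup:
    """A named set of equal-length sequences over one coordinate system.

    Parameters
    ----------
    name
        Group identifier, e.g. a continental population code such as ``"AF"``.
    sample_ids
        Ordered, unique sample identifiers.
    sequences
        Upper-case sequence strings, one per sample, all of equal length.
    """

    name: str
    sample_ids: list[str]
    sequences: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if self.M < 2:
            raise AlignmentError(
                f"group {self.name!r} needs at least 2 sequences, got {self.M}"
            )
        if len(set(self.sample_ids)) != self.M:
            raise AlignmentError(f"duplicate sample ids in group {self.name!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offender = next(
                sid
                for sid, s in zip(self.sample_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            )
            raise AlignmentError(
                f"unequal sequence lengths in group {self.name!r}: "
                f"record {offender!r} has length "
                f"{len(dict(zip(self.sample_ids, self.sequences))[offender])}, "
                f"expected {len(self.sequences[0])}"
            )

    @property
    def M(self) -> int:
        """Number of samples in the group."""
        return len(self.sequences)

    @property
    def L(self) -> int:
        """Alignment length in columns."""
        return len(self.sequences[0])

    def column(self, i: int) -> list[str]:
        """Return the M symbols of alignment column ``i`` (1-based) in sample order."""
        if not 1 <= i <= self.L:
            raise IndexError(f"position {i} out of range 1..{self.L}")
        return [s[i - 1] for s in self.sequences]

    def matrix(self) -> np.ndarray:
        """M x L array of single-byte symbols (cached).

        Column ``i`` (1-based) is ``matrix()[:, i - 1]``.
        """
        if self._matrix is None:
            raw = "".join(self.sequences).encode("ascii")
            self._matrix = np.frombuffer(raw, dtype="S1").reshape(self.M, self.L)
        return self._matrix

    def nonstandard_positions(self) -> set[int]:
        """1-based columns containing any symbol outside {A, C, G, T}."""
        mat = self.matrix()
        valid = np.zeros(mat.shape, dtype=bool)
        for sym in b"ACGT":
            valid |= mat == bytes([sym])
        cols = np.nonzero(~valid.all(axis=0))[0]
        return {int(c) + 1 for c in cols}


def read_group(fasta_path: str | Path, name: str) -> AlignedGroup:
    """Read one group's multi-FASTA of end-to-end aligned sequences.

    Symbols are upper-cased; all aligned-group invariants are enforced.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")
    sample_ids = [r.id for r in records]
    sequences = [str(r.seq).upper() for r in records]
    return AlignedGroup(name=name, sample_ids=sample_ids, sequences=sequences)


def write_group(group: AlignedGroup, fasta_path: str | Path) -> None:
    """Write a group back to multi-FASTA (inverse of :func:`read_group`)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(group.sample_ids, group.sequences)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def column(group: AlignedGroup, i: int) -> list[str]:
    """Module-level alias for :meth:`AlignedGroup.column`."""
    return group.column(i)


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Read a two-column manifest (group name, FASTA path), tab- or whitespace-split.

    Relative FASTA paths resolve against the manifest's directory. Lines that
    are empty or start with ``#`` are skipped.
    """
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        name, fasta = parts
        fasta_path = Path(fasta)
        if not fasta_path.is_absolute():
            fasta_path = path.parent / fasta_path
        entries.append((name, fasta_path))
    if not entries:
        raise InputError(f"manifest {path} lists no groups")
    return entries


def require_shared_coordinates(groups: Sequence[AlignedGroup]) -> int:
    """Assert all groups share one alignment length; return it."""
    lengths = {g.L for g in groups}
    if len(lengths) != 1:
        raise AlignmentError(
            f"groups disagree on alignment length: {sorted(lengths)}"
        )
    return lengths.pop()
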