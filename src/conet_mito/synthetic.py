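"""Synthetic aligned genome groups with planted co-segregation structure.

The generator emulates the statistical structure the pipeline assumes:
groups of end-to-end aligned genomes that differ from a shared reference
at (i) *planted blocks* — sets of positions whose variant states share
one carrier set per group, so every within-block position pair is a
perfect co-occurrence pair and every within-block triple a triangle —
and (ii) independent *noise sites* with random carrier sets. Carrier
sets are collision-checked (a set equal to, or complementary to, an
already-used set is redrawn) so the planted ground truth is exact.
Missing symbols (``N``) are sprinkled only over invariant columns by
default, because a missing observation inside a perfectly co-segregating
pair breaks exact co-occurrence under the full-M denominator.

No attempt is made to model realistic mtDNA mutation processes,
haplogroup phylogeny or rate heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment_io import AlignedGroup, write_group
from .annotation import Feature, GeneAnnotation, write_annotation

_BASES = "ACGT"

# Hmtdb-style continental group sizes (AF, AM, AS, EU, OC).
GROUP_SIZES = {"AF": 2323, "AM": 1692, "AS": 5715, "EU": 7142, "OC": 1539}
REFERENCE_ALIGNED_LENGTH = 16881


class SpecError(ValueError):
    """Invalid synthetic specification."""


@dataclass(frozen=True)
class PlantedBlock:
    """Positions sharing one carrier set per listed group."""

    positions: tuple[int, ...]
    carrier_fraction: float
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions) or len(self.positions) < 2:
            raise SpecError("block needs >= 2 distinct positions")
        if not 0 < self.carrier_fraction < 1:
            raise SpecError("carrier fraction must lie in (0, 1)")
        if not self.groups:
            raise SpecError("block must target >= 1 group")


@dataclass
class SyntheticSpec:
    L: int
    samples: dict[str, int]
    planted_blocks: list[PlantedBlock]
    genes: str | list[Feature] = "auto"
    noise_sites: int = 0
    noise_maf: tuple[float, float] = (0.02, 0.3)
    missing_rate: float = 0.0
    seed: int = 0
    allow_collisions: bool = False
    missing_in_blocks: bool = False

    def __post_init__(self) -> None:
        if self.L < 10:
            raise SpecError("alignment length too short")
        for g, m in self.samples.items():
            if m < 2:
                raise SpecError(f"group {g} needs M >= 2")
        seen: set[int] = set()
        for blk in self.planted_blocks:
            for pos in blk.positions:
                if not 1 <= pos <= self.L:
                    raise SpecError(f"block position {pos} out of range 1..{self.L}")
                if pos in seen:
                    raise SpecError(f"block position {pos} reused across blocks")
                seen.add(pos)
            unknown = set(blk.groups) - set(self.samples)
            if unknown:
                raise SpecError(f"block targets unknown groups {sorted(unknown)}")
        lo, hi = self.noise_maf
        if not 0 < lo <= hi < 0.5:
            raise SpecError("noise minor-allele frequency range must lie in (0, 0.5)")

    @property
    def block_positions(self) -> set[int]:
        return {p for blk in self.planted_blocks for p in blk.positions}


@dataclass
class GroundTruth:
    """Exact planted structure, per group."""

    pairs: dict[str, set[tuple[int, str, int, str]]]
    triangles: dict[str, set[tuple[int, int, int]]]
    carrier_counts: dict[str, dict[int, int]] = field(default_factory=dict)


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    reference: str
    groups: dict[str, AlignedGroup]
    annotation: GeneAnnotation
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> Path:
        """Write per-group FASTA, the feature table, ground truth and a spec echo."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_lines = []
        for name, group in self.groups.items():
            fasta = out / f"{name}.fasta"
            write_group(group, fasta)
            manifest_lines.append(f"{name}\t{fasta.name}")
        (out / "groups.tsv").write_text("\n".join(manifest_lines) + "\n")
        write_annotation(self.annotation, out / "features.tsv")
        (out / "reference.fasta").write_text(
            ">reference\n" + self.reference + "\n"
        )
        pair_rows = [
            {"group": g, "i": i, "x": x, "j": j, "y": y}
            for g, pairs in self.truth.pairs.items()
            for (i, x, j, y) in sorted(pairs)
        ]
        pd.DataFrame(pair_rows, columns=["group", "i", "x", "j", "y"]).to_csv(
            out / "truth_pairs.tsv", sep="\t", index=False
        )
        tri_rows = [
            {"group": g, "i": i, "j": j, "k": k}
            for g, tris in self.truth.triangles.items()
            for (i, j, k) in sorted(tris)
        ]
        pd.DataFrame(tri_rows, columns=["group", "i", "j", "k"]).to_csv(
            out / "truth_triangles.tsv", sep="\t", index=False
        )
        blocks = [
            {
                "positions": ",".join(map(str, blk.positions)),
                "carrier_fraction": blk.carrier_fraction,
                "groups": ",".join(blk.groups),
            }
            for blk in self.spec.planted_blocks
        ]
        pd.DataFrame(
            blocks, columns=["positions", "carrier_fraction", "groups"]
        ).to_csv(out / "truth_blocks.tsv", sep="\t", index=False)
        (out / "spec.yaml").write_text(yaml.safe_dump(_spec_echo(self.spec)))
        return out


def _spec_echo(spec: SyntheticSpec) -> dict:
    return {
        "L": spec.L,
        "samples": dict(spec.samples),
        "noise_sites": spec.noise_sites,
        "noise_maf": list(spec.noise_maf),
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
        "n_planted_blocks": len(spec.planted_blocks),
    }


def _alt_base(ref: str) -> str:
    """Fixed non-reference substitution: the next base in A->C->G->T->A order."""
    return _BASES[(_BASES.index(ref) + 1) % 4]


def auto_genes(L: int) -> list[Feature]:
    """Tile the reference with D-Loop, alternating-strand CDS, tRNA, rRNA and
    an ORIL block, leaving short Misc gaps — a cartoon of an organellar genome."""
    features: list[Feature] = []
    pos = 1
    dloop_len = min(200, max(20, L // 12))
    features.append(Feature("D-Loop", pos, pos + dloop_len - 1, "+", "D-Loop"))
    pos += dloop_len
    gene_idx = 0
    placed_oril = False
    cycle = [("tRNA", 69), ("CDS", 300), ("tRNA", 69), ("CDS", 300), ("rRNA", 150)]
    while pos <= L - 10:
        for kind, length in cycle:
            if pos + length - 1 > L:
                return features
            gene_idx += 1
            strand = "-" if (kind == "CDS" and gene_idx % 4 == 0) else "+"
            features.append(
                Feature(f"{kind[0]}{gene_idx}", pos, pos + length - 1, strand, kind)
            )
            pos += length + 5  # Misc gap between features
            if not placed_oril and pos + 50 <= L:
                features.append(Feature("ORIL", pos, pos + 49, "+", "ORIL"))
                pos += 55
                placed_oril = True
    return features


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw reference, annotation and per-group alignments with exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    ref_arr = rng.integers(0, 4, size=spec.L)
    reference = "".join(_BASES[b] for b in ref_arr)

    if spec.genes == "auto":
        features = auto_genes(spec.L)
    else:
        features = list(spec.genes)
    annotation = GeneAnnotation(features=features, reference_length=spec.L)

    groups: dict[str, AlignedGroup] = {}
    truth = GroundTruth(pairs={}, triangles={}, carrier_counts={})
    for gname, M in spec.samples.items():
        seqs = np.frombuffer(
            (reference * M).encode("ascii"), dtype="S1"
        ).reshape(M, spec.L).copy()
        used_sets: set[frozenset[int]] = set()
        variant_positions: set[int] = set()
        minor_state: dict[int, str] = {}
        truth.pairs[gname] = set()
        truth.triangles[gname] = set()
        truth.carrier_counts[gname] = {}

        def _try_draw(count: int, tries: int) -> frozenset[int] | None:
            for _ in range(tries):
                cset = frozenset(
                    int(v) for v in rng.choice(M, size=count, replace=False)
                )
                comp = frozenset(range(M)) - cset
                if spec.allow_collisions or (
                    cset not in used_sets and comp not in used_sets
                ):
                    used_sets.add(cset)
                    used_sets.add(comp)
                    return cset
            return None

        def draw_carriers(count: int) -> frozenset[int]:
            # collision-free set of the requested size, escalating to nearby
            # sizes when that size class is exhausted (small M)
            cset = _try_draw(count, 200)
            if cset is not None:
                return cset
            for delta in range(1, M):
                for cand in (count + delta, count - delta):
                    if 1 <= cand <= M - 1:
                        cset = _try_draw(cand, 200)
                        if cset is not None:
                            return cset
            raise SpecError(
                f"carrier-set space exhausted for group {gname} (M={M})"
            )

        # planted blocks targeting this group
        for blk in spec.planted_blocks:
            if gname not in blk.groups:
                continue
            count = min(M - 1, max(1, math.ceil(blk.carrier_fraction * M)))
            carriers = draw_carriers(count)
            count = len(carriers)  # may differ after size escalation
            idx = np.fromiter(carriers, dtype=int)
            for pos in blk.positions:
                ref_sym = reference[pos - 1]
                alt = _alt_base(ref_sym)
                seqs[idx, pos - 1] = alt.encode()
                variant_positions.add(pos)
                truth.carrier_counts[gname][pos] = count
                # the pipeline's variant-only filter keeps the minor state
                if count < M - count:
                    minor_state[pos] = alt
                elif count > M - count:
                    minor_state[pos] = ref_sym
                else:  # exact tie: consensus is the alphabetically first state
                    minor_state[pos] = max(ref_sym, alt)
            for a in range(len(blk.positions)):
                for b in range(a + 1, len(blk.positions)):
                    i, j = sorted((blk.positions[a], blk.positions[b]))
                    truth.pairs[gname].add((i, minor_state[i], j, minor_state[j]))
                    for c in range(b + 1, len(blk.positions)):
                        tri = tuple(
                            sorted(
                                (
                                    blk.positions[a],
                                    blk.positions[b],
                                    blk.positions[c],
                                )
                            )
                        )
                        truth.triangles[gname].add(tri)

        # independent noise sites
        if spec.noise_sites:
            candidates = np.array(
                sorted(set(range(1, spec.L + 1)) - spec.block_positions)
            )
            chosen = rng.choice(candidates, size=spec.noise_sites, replace=False)
            for pos in sorted(int(p) for p in chosen):
                freq = rng.uniform(*spec.noise_maf)
                count = min(M - 1, max(1, round(freq * M)))
                carriers = draw_carriers(count)
                idx = np.fromiter(carriers, dtype=int)
                alt = _alt_base(reference[pos - 1])
                seqs[idx, pos - 1] = alt.encode()
                variant_positions.add(pos)

        # missing symbols over invariant columns only (default)
        if spec.missing_rate > 0:
            allowed = np.ones(spec.L, dtype=bool)
            if not spec.missing_in_blocks:
                for pos in variant_positions:
                    allowed[pos - 1] = False
            mask = rng.random((M, spec.L)) < spec.missing_rate
            mask &= allowed[None, :]
            seqs[mask] = b"N"

        sample_ids = [f"{gname}_{k:05d}" for k in range(M)]
        sequences = [
            seqs[k].tobytes().decode("ascii") for k in range(M)
        ]
        groups[gname] = AlignedGroup(
            name=gname, sample_ids=sample_ids, sequences=sequences
        )
    return SyntheticData(
        spec=spec,
        reference=reference,
        groups=groups,
        annotation=annotation,
        truth=truth,
    )


def continental_spec(scale: float, seed: int = 2018) -> SyntheticSpec:
    """A five-group spec shaped like the Hmtdb study: group sizes are
    ``scale`` times the continental sample sizes (AF 2323, AM 1692, AS 5715,
    EU 7142, OC 1539), and the planted structure — mostly three-position
    blocks, whose carriers see a triangle (mean degree 2) — yields sparse
    networks with group mean degree near 2.
    """
    if not 0 < scale <= 1:
        raise SpecError("scale must lie in (0, 1]")
    samples = {g: max(2, round(scale * s)) for g, s in GROUP_SIZES.items()}
    L = max(2000, round(scale * REFERENCE_ALIGNED_LENGTH))
    rng = np.random.default_rng(seed)

    group_names = list(GROUP_SIZES)
    shared_subsets: list[tuple[str, ...]] = [
        tuple(group_names),  # one block common to all five groups
        ("AF", "AS", "EU"),
        ("AS", "EU"),
        ("AF", "AM"),
    ]
    block_sizes = [3] * (8 * len(group_names)) + [3, 3, 2, 2] + [4]
    total_positions = sum(block_sizes)
    positions = rng.choice(L, size=total_positions, replace=False) + 1
    positions = [int(p) for p in positions]

    blocks: list[PlantedBlock] = []
    cursor = 0

    def take(n: int) -> tuple[int, ...]:
        nonlocal cursor
        out = tuple(positions[cursor : cursor + n])
        cursor += n
        return out

    for gname in group_names:
        for _ in range(8):
            blocks.append(
                PlantedBlock(
                    positions=take(3),
                    carrier_fraction=float(rng.uniform(0.1, 0.4)),
                    groups=(gname,),
                )
            )
    for subset, size in zip(shared_subsets, (3, 3, 2, 2)):
        blocks.append(
            PlantedBlock(
                positions=take(size),
                carrier_fraction=float(rng.uniform(0.1, 0.4)),
                groups=subset,
            )
        )
    blocks.append(
        PlantedBlock(
            positions=take(4),
            carrier_fraction=float(rng.uniform(0.1, 0.4)),
            groups=("AS",),
        )
    )
    return SyntheticSpec(
        L=L,
        samples=samples,
        planted_blocks=blocks,
        genes="auto",
        noise_sites=40,
        noise_maf=(0.02, 0.3),
        missing_rate=0.01,
        seed=seed,
    )
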