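"""End-to-end pipeline: groups -> variomes -> networks -> motifs -> null comparison.

Every summary number written by the pipeline is recomputable from the
stage outputs shipped alongside it (variome tables, pair tables,
per-genome edge lists, censuses); nothing is a write-only aggregate.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment_io import AlignedGroup, read_group, read_manifest, require_shared_coordinates
from .annotation import codon_labels, load_annotation, read_projection
from .cooccurrence import (
    build_genome_networks,
    build_pair_table,
    copair_segment_matrix,
    group_network_summary,
    predominant_pairs,
    write_network_edges,
    write_pair_table,
)
from .motifs import census, group_census
from .nullmodel import build_ensemble, compare, empirical_label_pool
from .variome import (
    extract_variome,
    overlap_table,
    segment_tally,
    variome_overlap,
    write_variome,
)

log = logging.getLogger("conet_mito")


@dataclass
class RunConfig:
    manifest: Path
    annotation: Path
    out_dir: Path
    projection: Path | None = None
    variant_only: bool = True
    min_carriers: int = 1
    count_gaps_as_state: bool = False
    tnm_rule: str = "node_subtraction"
    null_label_mode: str = "pooled"
    null_reps: int = 10_000
    seed: int = 0
    collapse_trna: bool = True
    top_n_pairs: int = 10

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.annotation = Path(self.annotation)
        self.out_dir = Path(self.out_dir)
        for p in (self.manifest, self.annotation):
            if not p.exists():
                raise FileNotFoundError(p)
        if self.projection is not None:
            self.projection = Path(self.projection)
            if not self.projection.exists():
                raise FileNotFoundError(self.projection)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, writing per-group and cross-group tables under ``out_dir``.

    On any stage failure the partial outputs are kept and a ``FAILED``
    marker file records the error before the exception propagates.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: RunConfig, out: Path) -> Path:
    groups: list[AlignedGroup] = [
        read_group(path, name) for name, path in read_manifest(config.manifest)
    ]
    L = require_shared_coordinates(groups)
    log.info("read %d groups, alignment length %d", len(groups), L)

    ann = load_annotation(config.annotation)
    projection = (
        read_projection(config.projection) if config.projection is not None else None
    )
    labeling = codon_labels(
        ann,
        alignment_length=L,
        projection=projection,
    )
    if labeling.frame_conflicts:
        pd.DataFrame(
            labeling.frame_conflicts, columns=["position", "kept_label", "other_label"]
        ).to_csv(out / "frame_conflicts.tsv", sep="\t", index=False)

    summary_rows = []
    variomes = {}
    networks_by_group = {}
    for group in groups:
        gdir = out / group.name
        gdir.mkdir(exist_ok=True)
        log.info("group %s: M=%d", group.name, group.M)

        v = extract_variome(group, count_gaps_as_state=config.count_gaps_as_state)
        variomes[group.name] = v
        write_variome(v, labeling, gdir / "variome.tsv")
        segment_tally(v, labeling, collapse_trna=config.collapse_trna).to_csv(
            gdir / "variome_segments.tsv", sep="\t", index=False
        )

        table = build_pair_table(
            group,
            v,
            variant_only=config.variant_only,
            min_carriers=config.min_carriers,
        )
        write_pair_table(table, gdir / "pair_table.tsv")

        networks = build_genome_networks(
            group, table, labeling, collapse_trna=config.collapse_trna
        )
        networks_by_group[group.name] = networks
        ndir = gdir / "networks"
        ndir.mkdir(exist_ok=True)
        for nw in networks:
            write_network_edges(nw, ndir / f"{nw.sample_id}.tsv")

        stats = group_network_summary(networks)
        summary_rows.append(
            {
                "group": group.name,
                "S": group.M,
                "N_V": v.n_sites,
                "n_co_mean": stats["n_co_mean"],
                "n_co_sd": stats["n_co_sd"],
                "e_mean": stats["e_mean"],
                "e_sd": stats["e_sd"],
                "k_mean": stats["k_mean"],
            }
        )

        copair_segment_matrix(networks, level="kind").to_csv(
            gdir / "segment_matrix.tsv", sep="\t", index=False
        )

        censuses = [census(nw, tnm_rule=config.tnm_rule) for nw in networks]
        real_table = group_census(censuses)
        real_table.to_csv(gdir / "motif_census.tsv", sep="\t", index=False)

        if round(stats["n_co_mean"]) >= 2 and stats["e_mean"] > 0:
            ensemble = build_ensemble(
                stats["n_co_mean"],
                stats["k_mean"],
                empirical_label_pool(networks),
                R=config.null_reps,
                seed=config.seed + zlib.crc32(group.name.encode()) % 10_000,
                group=group.name,
                label_mode=config.null_label_mode,
            )
            comparison = compare(real_table, ensemble)
            ensemble.null_table().to_csv(
                gdir / "null_census.tsv", sep="\t", index=False
            )
            comparison.to_csv(gdir / "null_comparison.tsv", sep="\t", index=False)
        else:
            log.info("group %s: networks too small for a null ensemble", group.name)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    names = [g.name for g in groups]
    if len(groups) >= 2:
        partition = variome_overlap(list(variomes.values()))
        overlap_table(partition, names).to_csv(
            out / "variome_overlap.tsv", sep="\t", index=False
        )
        predominant_pairs(
            networks_by_group, labeling, top_n=config.top_n_pairs
        ).to_csv(out / "predominant_pairs.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in asdict(config).items()
        },
        "groups": {g.name: {"M": g.M, "L": g.L} for g in groups},
        "seed": config.seed,
        "coordinates": "1-based inclusive alignment columns",
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
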