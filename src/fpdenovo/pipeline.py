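"""End-to-end orchestration: footprint calling, masking, iterative discovery
and downstream characterization, with a JSON manifest per run directory."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .discovery import DiscoveryParams, DiscoveryResult, iterative_discovery
from .downstream import (
    compare_to_database,
    genome_scan,
    region_enrichment,
)
from .footprints import (
    FootprintParams,
    call_footprints,
    differential_track,
    filter_by_size,
    footprints_to_bed,
    merge_footprints,
)
from .io_formats import (
    read_bed,
    read_fasta,
    read_motifs,
    read_score_track,
    write_motifs,
)
from .masking import mask_known, masking_report, scan_intervals
from .motif_model import motif_report

logger = logging.getLogger("fpdenovo")

__all__ = ["RunConfig", "run_discovery", "run_differential", "EmptyResult"]


class EmptyResult(RuntimeError):
    """Raised when a run legitimately produces nothing (e.g. no footprints)."""


DEFAULT_CONFIG: Dict[str, object] = {
    "track_dialect": "bedgraph",
    "mask_mode": "motif_location",
    "scan_quantile": 1e-4,
    "seed": 0,
    # footprint parameters
    "min_width": 6,
    "max_width": 60,
    "local_window": 200,
    "height_factor": 1.5,
    "flat_top_tolerance": 0.15,
    "merge_gap_max": 6,
    "merge_depth_frac": 0.5,
    "min_fp_size": 8,
    # discovery parameters
    "w_min": 6,
    "w_max": 15,
    "seeds_per_iteration": 3,
    "motifs_per_iteration": 3,
    "max_iterations": 30,
    "stagnation_limit": 3,
    "evalue_cap": 0.05,
    "merge_threshold": 0.4,
    "min_fragment_size": 6,
}


class RunConfig:
    """Flat key/value run configuration; unknown keys are rejected."""

    _PATH_KEYS = {
        "track",
        "track_a",
        "track_b",
        "genome",
        "motif_db",
        "peaks",
        "features",
        "gene_sets",
    }

    def __init__(self, **kwargs: object):
        self.values: Dict[str, object] = dict(DEFAULT_CONFIG)
        for key, value in kwargs.items():
            if value is None:
                continue
            if key not in DEFAULT_CONFIG and key not in self._PATH_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            self.values[key] = value

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def footprint_params(self) -> FootprintParams:
        v = self.values
        return FootprintParams(
            min_width=int(v["min_width"]),
            max_width=int(v["max_width"]),
            local_window=int(v["local_window"]),
            height_factor=float(v["height_factor"]),
            flat_top_tolerance=float(v["flat_top_tolerance"]),
            merge_gap_max=int(v["merge_gap_max"]),
            merge_depth_frac=float(v["merge_depth_frac"]),
            min_fp_size=int(v["min_fp_size"]),
        )

    def discovery_params(self) -> DiscoveryParams:
        v = self.values
        return DiscoveryParams(
            motif_width_range=(int(v["w_min"]), int(v["w_max"])),
            seeds_per_iteration=int(v["seeds_per_iteration"]),
            motifs_per_iteration=int(v["motifs_per_iteration"]),
            max_iterations=int(v["max_iterations"]),
            stagnation_limit=int(v["stagnation_limit"]),
            evalue_cap=float(v["evalue_cap"]),
            merge_threshold=float(v["merge_threshold"]),
            min_fragment_size=int(v["min_fragment_size"]),
            rng_seed=int(v["seed"]),
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, extra: Dict[str, object]) -> None:
    manifest = {
        "tool": "fpdenovo",
        "version": __version__,
        "parameters": {
            k: v for k, v in config.values.items() if k not in RunConfig._PATH_KEYS
        },
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(str(v))}
            for k, v in config.values.items()
            if k in RunConfig._PATH_KEYS and v is not None
        },
    }
    manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _discovery_outputs(
    outdir: Path, result: DiscoveryResult, genome: Dict[str, str]
) -> None:
    motif_dir = outdir / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for rec in result.iterations:
        if rec.motifs:
            write_motifs(
                rec.motifs,
                str(motif_dir / f"iteration_{rec.index:02d}.meme"),
                format="meme_minimal",
            )
    write_motifs(result.consensus, str(outdir / "consensus.jaspar"), format="jaspar")
    write_motifs(
        result.consensus, str(outdir / "consensus.meme"), format="meme_minimal"
    )
    (outdir / "consensus_report.tsv").write_text(motif_report(result.consensus))

    lines = ["iteration\tpool_size_before\tmotifs\tsignificant"]
    for rec in result.iterations:
        lines.append(
            f"{rec.index}\t{rec.pool_size_before}\t{len(rec.motifs)}\t"
            f"{sum(rec.significant)}"
        )
        logger.info(
            "iteration %d: pool=%d motifs=%d significant=%d",
            rec.index,
            rec.pool_size_before,
            len(rec.motifs),
            sum(rec.significant),
        )
    (outdir / "iterations.tsv").write_text("\n".join(lines) + "\n")


def _characterize(
    outdir: Path, result: DiscoveryResult, genome: Dict[str, str], config: RunConfig
) -> None:
    db_path = config.get("motif_db")
    if db_path and result.consensus:
        db = read_motifs(str(db_path), format="jaspar")
        matches, matrix = compare_to_database(
            result.consensus, db, float(config["merge_threshold"])
        )
        lines = ["motif\tbest_match\tdistance\tlabel"]
        for m in matches:
            label = "rediscovered" if m.rediscovered else "novel"
            lines.append(f"{m.motif_name}\t{m.best_match}\t{m.distance:.4f}\t{label}")
        (outdir / "database_comparison.tsv").write_text("\n".join(lines) + "\n")
        header = "motif\t" + "\t".join(d.name for d in db)
        rows = [header]
        for m, row in zip(result.consensus, matrix):
            rows.append(m.name + "\t" + "\t".join(f"{v:.4f}" for v in row))
        (outdir / "distance_matrix.tsv").write_text("\n".join(rows) + "\n")

    peaks_path = config.get("peaks")
    if peaks_path and result.consensus:
        peaks = read_bed(str(peaks_path))
        genome_bp = sum(len(s) for s in genome.values())
        lines = ["motif\thits_in_regions\thits_total\tfold\tp_value"]
        for m in result.consensus:
            hits = genome_scan(m, genome, float(config["scan_quantile"]))
            enr = region_enrichment(hits, peaks, genome_bp, motif_name=m.name)
            lines.append(
                f"{m.name}\t{enr.hits_in_regions}\t{enr.hits_total}\t"
                f"{enr.fold:.4f}\t{enr.p_value:.4g}"
            )
        (outdir / "region_enrichment.tsv").write_text("\n".join(lines) + "\n")


def _run_core(track, genome, config: RunConfig, outdir: Path) -> DiscoveryResult:
    fp_params = config.footprint_params()
    fps = call_footprints(track, fp_params)
    fps = merge_footprints(
        fps, track, fp_params.merge_gap_max, fp_params.merge_depth_frac
    )
    fps = filter_by_size(fps, fp_params.min_fp_size)
    footprints_to_bed(fps, str(outdir / "footprints.bed"))
    logger.info("called %d footprints", len(fps))
    if not fps:
        raise EmptyResult("no footprints called")

    n_before = len(fps)
    db_path = config.get("motif_db")
    if db_path:
        db = read_motifs(str(db_path), format="jaspar")
        hits = scan_intervals(
            genome, [fp.interval for fp in fps], db, float(config["scan_quantile"])
        )
        fps = mask_known(
            fps,
            hits,
            mode=str(config["mask_mode"]),
            min_fp_size=int(config["min_fp_size"]),
            track=track,
        )
        footprints_to_bed(fps, str(outdir / "footprints_masked.bed"))
        (outdir / "masking_report.tsv").write_text(masking_report(n_before, fps))
        logger.info("masking kept %d of %d footprints", len(fps), n_before)
        if not fps:
            raise EmptyResult("all footprints masked by the motif database")

    result = iterative_discovery(fps, genome, config.discovery_params())
    _discovery_outputs(outdir, result, genome)
    _characterize(outdir, result, genome, config)
    return result


def run_discovery(config: RunConfig, outdir: str) -> DiscoveryResult:
    """Single-condition end-to-end run; writes artifacts into ``outdir``."""
    for key in ("track", "genome"):
        if config.get(key) is None:
            raise ValueError(f"missing required input {key!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(str(config["genome"]))
    track = read_score_track(
        str(config["track"]),
        dialect=str(config["track_dialect"]),
        chrom_lengths={c: len(s) for c, s in genome.items()},
    )
    result = _run_core(track, genome, config, out)
    _write_manifest(
        out,
        config,
        {"mode": "discovery", "consensus_motifs": len(result.consensus)},
    )
    return result


def run_differential(config: RunConfig, outdir: str) -> DiscoveryResult:
    """Two-condition run: footprints are called on max(0, A - B)."""
    for key in ("track_a", "track_b", "genome"):
        if config.get(key) is None:
            raise ValueError(f"missing required input {key!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(str(config["genome"]))
    lengths = {c: len(s) for c, s in genome.items()}
    dialect = str(config["track_dialect"])
    track_a = read_score_track(str(config["track_a"]), dialect, lengths)
    track_b = read_score_track(str(config["track_b"]), dialect, lengths)
    diff = differential_track(track_a, track_b)
    result = _run_core(diff, genome, config, out)
    _write_manifest(
        out,
        config,
        {
            "mode": "differential",
            "condition_order": ["track_a", "track_b"],
            "consensus_motifs": len(result.consensus),
        },
    )
    return result
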