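"""Motif characterization: genome scanning, region enrichment, feature
annotation, gene-set enrichment, database comparison and TF-class assignment
via binding-site overlap, plus aggregate signal profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import Feature, GenomicInterval, ScoreTrack
from .masking import scan_intervals
from .motif_model import Motif, MotifHit, motif_distance

__all__ = [
    "RegionEnrichment",
    "TFClassEnrichment",
    "AnnotationRecord",
    "DatabaseMatch",
    "genome_scan",
    "region_enrichment",
    "annotate_hits",
    "gsea",
    "compare_to_database",
    "binding_site_overlap",
    "tf_class_enrichment",
    "aggregate_profile",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class RegionEnrichment:
    motif_name: str
    hits_in_regions: int
    hits_total: int
    region_bp: int
    genome_bp: int
    fold: float
    p_value: float
    undefined: bool = False  # set when hits_total == 0


@dataclass(frozen=True)
class TFClassEnrichment:
    tf_class: str
    n: int
    N: int
    dn: int
    DN: int
    fold: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class AnnotationRecord:
    hit: MotifHit
    feature_name: str
    distance: int  # signed bp from hit midpoint to feature anchor; 0 if overlapping


@dataclass(frozen=True)
class DatabaseMatch:
    motif_name: str
    best_match: str
    distance: float
    rediscovered: bool  # strictly below the distance threshold


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values, preserving input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    n = len(p)
    if n == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def genome_scan(
    motif: Motif,
    genome: Mapping[str, str],
    threshold_quantile: float = 1e-4,
    background: Optional[np.ndarray] = None,
) -> List[MotifHit]:
    """Scan whole chromosomes for motif occurrences on both strands."""
    intervals = [
        GenomicInterval(chrom, 0, len(seq))
        for chrom, seq in genome.items()
        if len(seq) >= motif.width
    ]
    return scan_intervals(genome, intervals, [motif], threshold_quantile, background)


def _merge_regions(regions: Sequence[GenomicInterval]) -> Dict[str, List[Tuple[int, int]]]:
    per: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        per.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, blocks in per.items():
        blocks.sort()
        merged = [blocks[0]]
        for s, e in blocks[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        per[chrom] = merged
    return per


def _hit_in_regions(hit: MotifHit, merged: Dict[str, List[Tuple[int, int]]]) -> bool:
    blocks = merged.get(hit.interval.chrom)
    if not blocks:
        return False
    starts = [b[0] for b in blocks]
    i = np.searchsorted(starts, hit.interval.end) - 1
    for j in (i, i + 1):
        if 0 <= j < len(blocks):
            s, e = blocks[j]
            if s < hit.interval.end and hit.interval.start < e:
                return True
    return False


def region_enrichment(
    hits: Sequence[MotifHit],
    regions: Sequence[GenomicInterval],
    genome_bp: int,
    motif_name: str = "",
) -> RegionEnrichment:
    """Enrichment of hits inside regions against the whole genome.

    fold = (hits_in / region_bp) / (hits_total / genome_bp); p is the
    one-sided binomial tail with p0 = region_bp / genome_bp.
    """
    merged = _merge_regions(regions)
    region_bp = sum(e - s for blocks in merged.values() for s, e in blocks)
    if genome_bp < region_bp:
        raise ValueError("genome_bp must be >= total region bp")
    total = len(hits)
    if total == 0:
        return RegionEnrichment(motif_name, 0, 0, region_bp, genome_bp, 0.0, 1.0, True)
    inside = sum(_hit_in_regions(h, merged) for h in hits)
    p0 = region_bp / genome_bp
    fold = (inside / region_bp) / (total / genome_bp) if region_bp > 0 else 0.0
    p = float(stats.binom.sf(inside - 1, total, p0)) if inside > 0 else 1.0
    return RegionEnrichment(motif_name, inside, total, region_bp, genome_bp, fold, p)


def annotate_hits(
    hits: Sequence[MotifHit],
    features: Sequence[Feature],
    max_distance: int = 10_000,
) -> List[AnnotationRecord]:
    """Assign each hit the nearest feature anchor within ``max_distance``.

    The anchor is the strand-aware feature start (interval end for minus
    strand). Overlapping features count as distance 0. Ties go to the
    lexicographically smaller feature name. Hits without a feature in range
    are omitted.
    """
    per_chrom: Dict[str, List[Feature]] = {}
    for f in features:
        per_chrom.setdefault(f.interval.chrom, []).append(f)

    records = []
    for hit in hits:
        mid = hit.interval.midpoint
        best: Optional[Tuple[int, str]] = None
        for f in per_chrom.get(hit.interval.chrom, []):
            if hit.interval.overlaps(f.interval):
                dist = 0
            else:
                anchor = (
                    f.interval.end if f.interval.strand == "-" else f.interval.start
                )
                dist = anchor - mid
            if abs(dist) > max_distance:
                continue
            key = (abs(dist), f.name)
            if best is None or key < (abs(best[0]), best[1]):
                best = (dist, f.name)
        if best is not None:
            records.append(AnnotationRecord(hit, best[1], best[0]))
    return records


def gsea(
    genes: set,
    gene_sets: Mapping[str, Sequence[str]],
    universe: set,
) -> List[Tuple[str, int, float, float, float]]:
    """Hypergeometric over-representation per gene set.

    Returns ``(set name, overlap, fold, p, BH q)`` tuples in sorted set-name
    order. p = P[X >= k] drawing |genes| from the universe with
    |set ∩ universe| successes.
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("genes must be a subset of the universe")
    M, n_draw = len(universe), len(genes)
    names = sorted(gene_sets)
    rows = []
    for name in names:
        members = set(gene_sets[name]) & universe
        k = len(genes & members)
        K = len(members)
        if k > 0:
            p = float(stats.hypergeom.sf(k - 1, M, K, n_draw))
        else:
            p = 1.0
        expected = n_draw * K / M
        fold = (k / expected) if expected > 0 else 0.0
        rows.append((name, k, fold, p))
    qs = benjamini_hochberg([r[3] for r in rows])
    return [(name, k, fold, p, float(q)) for (name, k, fold, p), q in zip(rows, qs)]


def compare_to_database(
    consensus_motifs: Sequence[Motif],
    db_motifs: Sequence[Motif],
    threshold: float = 0.4,
) -> Tuple[List[DatabaseMatch], np.ndarray]:
    """Best database match per motif plus the full distance matrix.

    A motif is "rediscovered" iff its minimum distance is strictly below the
    threshold; otherwise it is "novel".
    """
    if not db_motifs:
        raise ValueError("database must be non-empty")
    matrix = np.zeros((len(consensus_motifs), len(db_motifs)))
    matches = []
    for i, m in enumerate(consensus_motifs):
        for j, db in enumerate(db_motifs):
            matrix[i, j] = motif_distance(m, db)
        j_best = int(np.argmin(matrix[i]))
        dist = float(matrix[i, j_best])
        matches.append(
            DatabaseMatch(m.name, db_motifs[j_best].name, dist, dist < threshold)
        )
    return matches, matrix


def binding_site_overlap(
    hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit]
) -> float:
    """Overlap coefficient: fraction of the smaller hit set sharing >= 1 bp
    with a hit of the other set (each hit counted once)."""
    if not hits_a or not hits_b:
        return 0.0
    small, large = (hits_a, hits_b) if len(hits_a) <= len(hits_b) else (hits_b, hits_a)
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for h in large:
        per_chrom.setdefault(h.interval.chrom, []).append(
            (h.interval.start, h.interval.end)
        )
    for blocks in per_chrom.values():
        blocks.sort()
    count = 0
    for h in small:
        blocks = per_chrom.get(h.interval.chrom, [])
        if not blocks:
            continue
        starts = [b[0] for b in blocks]
        i = int(np.searchsorted(starts, h.interval.end))
        for j in range(max(0, i - 50), i):  # window back over candidates
            s, e = blocks[j]
            if s < h.interval.end and h.interval.start < e:
                count += 1
                break
    return count / len(small)


def tf_class_enrichment(
    target_hits: Sequence[MotifHit],
    db_motifs: Sequence[Motif],
    db_hits: Mapping[str, Sequence[MotifHit]],
    percentile: float = 95.0,
) -> List[TFClassEnrichment]:
    """TF-class assignment via binding-site overlap.

    Database motifs without a ``class`` metadata label are excluded. N is the
    set of database motifs whose overlap with the target exceeds the given
    percentile of the (per-target) overlap distribution; for each class,
    n of N and dn of DN members give fold = (n/N)/(dn/DN) and a
    hypergeometric p-value P[X >= n], BH-corrected across classes.
    Returns an empty list when N is empty.
    """
    classed = [m for m in db_motifs if m.metadata.get("class")]
    if not classed:
        return []
    overlaps = {
        m.name: binding_site_overlap(target_hits, db_hits.get(m.name, []))
        for m in classed
    }
    values = np.array([overlaps[m.name] for m in classed])
    cutoff = float(np.percentile(values, percentile))
    top = [m for m in classed if overlaps[m.name] > cutoff]
    N, DN = len(top), len(classed)
    if N == 0:
        return []
    classes = sorted({m.metadata["class"] for m in classed})
    rows = []
    for cls in classes:
        n = sum(1 for m in top if m.metadata["class"] == cls)
        dn = sum(1 for m in classed if m.metadata["class"] == cls)
        fold = (n / N) / (dn / DN) if dn > 0 else 0.0
        p = float(stats.hypergeom.sf(n - 1, DN, dn, N)) if n > 0 else 1.0
        rows.append((cls, n, dn, fold, p))
    qs = benjamini_hochberg([r[4] for r in rows])
    return [
        TFClassEnrichment(cls, n, N, dn, DN, fold, p, float(q))
        for (cls, n, dn, fold, p), q in zip(rows, qs)
    ]


def aggregate_profile(
    track: ScoreTrack,
    hits: Sequence[MotifHit],
    flank_bp: int = 60,
) -> Tuple[np.ndarray, int]:
    """Mean signal in windows of width 2*flank_bp centered on hit midpoints.

    Minus-strand windows are reversed. Only hits with fully in-bounds windows
    contribute; returns (profile, number of hits used).
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    width = 2 * flank_bp
    total = np.zeros(width)
    used = 0
    for h in hits:
        if h.interval.chrom not in track:
            continue
        vec = track[h.interval.chrom]
        mid = h.interval.midpoint
        lo, hi = mid - flank_bp, mid + flank_bp
        if lo < 0 or hi > len(vec):
            continue
        window = vec[lo:hi]
        total += window[::-1] if h.strand == "-" else window
        used += 1
    if used == 0:
        raise ValueError("no hit with a fully in-bounds window")
    return total / used, used
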