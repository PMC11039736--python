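"""Footprint calling from per-base score tracks.

A footprint candidate is a maximal run of positions whose score exceeds both
zero and a local, window-averaged height limit. Retained candidates must fall
within a width range and pass a flat-top test: the positions scoring at least
(1 - tolerance) times the region maximum must form one contiguous run of at
least two bases (regions narrower than 4 bp are exempt). Nearby footprints
are merged when the gap between them is short and the signal in the gap does
not drop too far below the flanking maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List

import numpy as np

from .io_formats import GenomicInterval, ScoreTrack, write_bed

__all__ = [
    "Footprint",
    "FootprintParams",
    "local_threshold",
    "call_footprints",
    "merge_footprints",
    "differential_track",
    "filter_by_size",
    "footprints_to_bed",
]

FLAT_TOP_EXEMPT_WIDTH = 4  # regions narrower than this skip the flat-top test


@dataclass(frozen=True)
class Footprint:
    interval: GenomicInterval
    max_score: float
    mean_score: float
    summit: int  # offset of the leftmost maximum within the interval

    def __post_init__(self) -> None:
        if self.max_score < self.mean_score - 1e-9 or self.mean_score < 0:
            raise ValueError("require max_score >= mean_score >= 0")
        if not (0 <= self.summit < self.interval.width):
            raise ValueError("summit outside interval")

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class FootprintParams:
    min_width: int = 6
    max_width: int = 60
    local_window: int = 200
    height_factor: float = 1.5
    flat_top_tolerance: float = 0.15
    merge_gap_max: int = 6
    merge_depth_frac: float = 0.5
    min_fp_size: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.min_width <= self.max_width):
            raise ValueError("require 0 < min_width <= max_width")
        if not (0 < self.flat_top_tolerance < 1):
            raise ValueError("flat_top_tolerance must be in (0, 1)")
        if not (0 <= self.merge_depth_frac <= 1):
            raise ValueError("merge_depth_frac must be in [0, 1]")
        if self.local_window < 1:
            raise ValueError("local_window must be >= 1")


def local_threshold(
    scores: np.ndarray, local_window: int, height_factor: float
) -> np.ndarray:
    """Per-base threshold: height_factor times the centered windowed mean.

    The window is truncated at chromosome ends (the mean divides by the
    number of in-bounds positions). Even windows are widened by one.
    """
    if local_window < 1:
        raise ValueError("local_window must be >= 1")
    if local_window % 2 == 0:
        local_window += 1
    scores = np.asarray(scores, dtype=np.float64)
    n = len(scores)
    if n == 0:
        return np.zeros(0)
    half = local_window // 2
    csum = np.concatenate(([0.0], np.cumsum(scores)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return height_factor * means


def _flat_top_ok(region: np.ndarray, tolerance: float) -> bool:
    if len(region) < FLAT_TOP_EXEMPT_WIDTH:
        return True
    plateau = region >= (1.0 - tolerance) * region.max()
    idx = np.flatnonzero(plateau)
    contiguous = idx[-1] - idx[0] + 1 == len(idx)
    return contiguous and len(idx) >= 2


def _make_footprint(chrom: str, start: int, scores: np.ndarray) -> Footprint:
    region = scores
    summit = int(np.argmax(region))
    return Footprint(
        interval=GenomicInterval(chrom, start, start + len(region)),
        max_score=float(region.max()),
        mean_score=float(region.mean()),
        summit=summit,
    )


def call_footprints(track: ScoreTrack, params: FootprintParams) -> List[Footprint]:
    """Call footprints on every chromosome; sorted by (chrom, start)."""
    out: List[Footprint] = []
    for chrom in sorted(track.chroms):
        scores = track[chrom]
        if len(scores) == 0:
            continue
        thr = local_threshold(scores, params.local_window, params.height_factor)
        above = (scores > thr) & (scores > 0)
        padded = np.concatenate(([False], above, [False]))
        diffs = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diffs == 1)
        ends = np.flatnonzero(diffs == -1)
        for s, e in zip(starts, ends):
            width = e - s
            if not (params.min_width <= width <= params.max_width):
                continue
            region = scores[s:e]
            if not _flat_top_ok(region, params.flat_top_tolerance):
                continue
            out.append(_make_footprint(chrom, int(s), region))
    return out


def merge_footprints(
    fps: List[Footprint],
    track: ScoreTrack,
    merge_gap_max: int,
    merge_depth_frac: float,
) -> List[Footprint]:
    """Merge adjacent footprints separated by short, shallow gaps.

    Two neighbours merge when the gap is strictly below ``merge_gap_max`` bp
    and the minimum track score in the gap is at least ``merge_depth_frac``
    times the smaller of the two maxima. Merging proceeds left to right and
    is re-evaluated transitively; merged statistics are recomputed from the
    track.
    """
    by_chrom: Dict[str, List[Footprint]] = {}
    prev_key = None
    for fp in fps:
        key = (fp.interval.chrom, fp.interval.start)
        if prev_key is not None and key < prev_key:
            raise ValueError("footprints must be sorted by (chrom, start)")
        prev_key = key
        by_chrom.setdefault(fp.interval.chrom, []).append(fp)

    out: List[Footprint] = []
    for chrom in sorted(by_chrom):
        scores = track[chrom]
        current = by_chrom[chrom][0]
        for nxt in by_chrom[chrom][1:]:
            gap = nxt.interval.start - current.interval.end
            gap_min = (
                float(scores[current.interval.end : nxt.interval.start].min())
                if gap > 0
                else np.inf
            )
            depth_limit = merge_depth_frac * min(current.max_score, nxt.max_score)
            if gap < merge_gap_max and gap_min >= depth_limit:
                s, e = current.interval.start, nxt.interval.end
                current = _make_footprint(chrom, s, scores[s:e])
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def differential_track(a: ScoreTrack, b: ScoreTrack) -> ScoreTrack:
    """Pointwise max(0, a - b); chromosome sets and lengths must match."""
    if a.lengths != b.lengths:
        raise ValueError(
            f"mismatched chromosomes/lengths: {a.lengths} vs {b.lengths}"
        )
    return ScoreTrack(
        {chrom: np.maximum(0.0, a[chrom] - b[chrom]) for chrom in a.chroms}
    )


def filter_by_size(fps: List[Footprint], min_fp_size: int) -> List[Footprint]:
    return [fp for fp in fps if fp.width >= min_fp_size]


def footprints_to_bed(fps: List[Footprint], path: str) -> None:
    """Export as BED6: name = index, score = max_score*1000 clipped to 0-1000."""
    intervals = [fp.interval for fp in fps]
    names = [str(i) for i in range(len(fps))]
    scores = [min(1000.0, max(0.0, fp.max_score * 1000.0)) for fp in fps]
    write_bed(intervals, path, names=names, scores=scores)
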