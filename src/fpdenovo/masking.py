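"""PWM scanning and removal of footprint regions explained by known motifs.

Per-motif hit thresholds come from the exact distribution of log-odds scores
of random W-mers under the background model, computed by dynamic programming
over per-column score distributions discretized to 0.01 bins. A hit requires
a log-odds score at or above the smallest score whose upper tail probability
is at most the requested quantile.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .footprints import Footprint
from .io_formats import GenomicInterval, ScoreTrack
from .motif_model import Motif, MotifHit, pfm_to_pwm, uniform_background

__all__ = [
    "pwm_score_threshold",
    "scan_sequence",
    "scan_intervals",
    "mask_known",
    "hits_to_bed",
    "masking_report",
]

_SCORE_BIN = 0.01


def pwm_score_threshold(
    pwm: np.ndarray, background: np.ndarray, quantile: float
) -> float:
    """Smallest score t with P[score(random W-mer) >= t] <= quantile.

    Exact under the mononucleotide background, on a 0.01-binned score grid.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    q = np.round(pwm / _SCORE_BIN).astype(np.int64)
    lo = int(q.min(axis=0).sum())
    hi = int(q.max(axis=0).sum())
    dist = np.array([1.0])
    offset = 0  # dist[i] = P[partial score == offset + i]
    for j in range(q.shape[1]):
        col = np.zeros(q[:, j].max() - q[:, j].min() + 1)
        cmin = q[:, j].min()
        for b in range(4):
            col[q[b, j] - cmin] += background[b]
        dist = np.convolve(dist, col)
        offset += cmin
    assert offset == lo and offset + len(dist) - 1 == hi
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P[score >= offset + i]
    idx = np.searchsorted(-tail, -quantile)  # first index with tail <= quantile
    if idx >= len(tail):
        idx = len(tail) - 1
    return (offset + idx) * _SCORE_BIN


_ENCODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) & 0x7F]


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Binned log-odds of every window; windows containing non-ACGT get -inf.

    Scores use the same 0.01 binning as :func:`pwm_score_threshold` so that
    thresholds and scan scores live on an identical grid.
    """
    w = pwm.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    q = np.round(pwm / _SCORE_BIN) * _SCORE_BIN
    padded = np.vstack([q, np.full((1, w), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return padded[windows, np.arange(w)].sum(axis=1)


def scan_sequence(
    seq: str,
    pwm: np.ndarray,
    threshold: float,
) -> List[Tuple[int, str, float]]:
    """Scan both strands; returns (offset, strand, llr) for scores >= threshold."""
    codes = encode_sequence(seq)
    eps = _SCORE_BIN / 100.0  # guard against float summation jitter on the grid
    hits: List[Tuple[int, str, float]] = []
    fwd = _window_scores(codes, pwm)
    rc_pwm = pwm[::-1, ::-1]
    rev = _window_scores(codes, rc_pwm)
    for j in np.flatnonzero(fwd >= threshold - eps):
        hits.append((int(j), "+", float(fwd[j])))
    for j in np.flatnonzero(rev >= threshold - eps):
        hits.append((int(j), "-", float(rev[j])))
    hits.sort()
    return hits


def scan_intervals(
    genome: Mapping[str, str],
    intervals: Sequence[GenomicInterval],
    motifs: Sequence[Motif],
    threshold_quantile: float = 1e-4,
    background: Optional[np.ndarray] = None,
) -> List[MotifHit]:
    """Scan interval sequences with every motif; hits in genome coordinates.

    Sequences shorter than a motif simply yield no hits for that motif.
    """
    bg = uniform_background() if background is None else np.asarray(background)
    out: List[MotifHit] = []
    prepared = []
    for m in motifs:
        pwm = pfm_to_pwm(m, bg)
        prepared.append((m, pwm, pwm_score_threshold(pwm, bg, threshold_quantile)))
    for iv in intervals:
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} out of bounds")
        sub = seq[iv.start : iv.end]
        for m, pwm, thr in prepared:
            for off, strand, score in scan_sequence(sub, pwm, thr):
                out.append(
                    MotifHit(
                        motif_name=m.name,
                        interval=GenomicInterval(
                            iv.chrom, iv.start + off, iv.start + off + m.width
                        ),
                        strand=strand,
                        llr_score=score,
                    )
                )
    out.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.motif_name))
    return out


def _subtract_intervals(
    start: int, end: int, blocks: List[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """Fragments of [start, end) not covered by the (merged) blocks."""
    frags = []
    cursor = start
    for bs, be in blocks:
        bs, be = max(bs, start), min(be, end)
        if bs >= be:
            continue
        if bs > cursor:
            frags.append((cursor, bs))
        cursor = max(cursor, be)
    if cursor < end:
        frags.append((cursor, end))
    return frags


def _merge_blocks(blocks: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not blocks:
        return []
    blocks = sorted(blocks)
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mask_known(
    fps: Sequence[Footprint],
    hits: Sequence[MotifHit],
    mode: str = "motif_location",
    min_fp_size: int = 8,
    track: Optional[ScoreTrack] = None,
) -> List[Footprint]:
    """Remove footprint portions explained by known-motif hits.

    mode "whole_fp": drop any footprint overlapping a hit by >= 1 bp.
    mode "motif_location": subtract the union of overlapping hit intervals
    from each footprint; fragments of at least ``min_fp_size`` bp survive with
    scores recomputed from ``track`` when given, else inherited.
    """
    if mode not in ("motif_location", "whole_fp"):
        raise ValueError(f"unknown mode {mode!r}")
    hits_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for h in hits:
        hits_by_chrom.setdefault(h.interval.chrom, []).append(
            (h.interval.start, h.interval.end)
        )
    for chrom in hits_by_chrom:
        hits_by_chrom[chrom] = _merge_blocks(hits_by_chrom[chrom])

    out: List[Footprint] = []
    for fp in fps:
        iv = fp.interval
        blocks = [
            (s, e)
            for s, e in hits_by_chrom.get(iv.chrom, [])
            if s < iv.end and e > iv.start
        ]
        if not blocks:
            out.append(fp)
            continue
        if mode == "whole_fp":
            continue
        for fs, fe in _subtract_intervals(iv.start, iv.end, blocks):
            if fe - fs < min_fp_size:
                continue
            if track is not None and iv.chrom in track:
                region = track[iv.chrom][fs:fe]
                out.append(
                    Footprint(
                        interval=GenomicInterval(iv.chrom, fs, fe),
                        max_score=float(region.max()),
                        mean_score=float(region.mean()),
                        summit=int(np.argmax(region)),
                    )
                )
            else:
                out.append(
                    Footprint(
                        interval=GenomicInterval(iv.chrom, fs, fe),
                        max_score=fp.max_score,
                        mean_score=fp.mean_score,
                        summit=0,
                    )
                )
    return out


def hits_to_bed(hits: Sequence[MotifHit], path: str) -> None:
    from .io_formats import write_bed

    intervals = [
        GenomicInterval(h.interval.chrom, h.interval.start, h.interval.end, h.strand)
        for h in hits
    ]
    names = [h.motif_name for h in hits]
    scores = [h.llr_score for h in hits]
    write_bed(intervals, path, names=names, scores=scores)


def masking_report(n_before: int, fps_after: Sequence[Footprint]) -> str:
    return (
        "footprints_before\tfootprints_after\n"
        f"{n_before}\t{len(fps_after)}\n"
    )
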