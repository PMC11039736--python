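"""Position-frequency-matrix model: scoring, information content, similarity
distance and consensus merging.

The similarity distance is 1 minus the best overlap-weighted mean per-column
Pearson correlation over all ungapped alignments with at least four
overlapping columns, evaluated against both the motif and its reverse
complement. The alignment score is down-weighted by
``overlap / min(width1, width2)`` so that a full-width match of the shorter
motif scores its plain mean correlation while short lucky overlaps between
unrelated motifs are discounted. The default merging threshold of 0.4 is
applied as a strict upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import GenomicInterval

__all__ = [
    "Motif",
    "MotifHit",
    "BASES",
    "uniform_background",
    "background_from_sequences",
    "pfm_to_pwm",
    "information_content",
    "reverse_complement_motif",
    "motif_distance",
    "cluster_and_merge",
    "motif_report",
]

BASES = "ACGT"
MIN_OVERLAP = 4


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def background_from_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Empirical mononucleotide frequencies of a sequence pool (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        for bi, base in enumerate(BASES):
            counts[bi] += seq.count(base)
    if counts.sum() == 0:
        return uniform_background()
    # keep all entries positive so log-odds stay finite
    counts += 1.0
    return counts / counts.sum()


class Motif:
    """A motif as a 4xW count matrix (rows A,C,G,T).

    Columns are rescaled on construction so that every column sums to
    ``nsites``; when ``nsites`` is omitted it is taken from the first column
    sum of the input matrix.
    """

    def __init__(
        self,
        counts: np.ndarray,
        nsites: Optional[float] = None,
        name: str = "motif",
        evalue: Optional[float] = None,
        source: Optional[str] = None,
        metadata: Optional[Dict[str, str]] = None,
    ):
        counts = np.asarray(counts, dtype=np.float64)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"counts must be 4xW, got shape {counts.shape}")
        if counts.shape[1] < MIN_OVERLAP:
            raise ValueError(f"motif width must be >= {MIN_OVERLAP}")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        colsums = counts.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError("motif has an empty column")
        if nsites is None:
            nsites = float(colsums[0])
        if nsites <= 0:
            raise ValueError("nsites must be positive")
        self.counts = counts * (nsites / colsums)
        self.nsites = float(nsites)
        self.name = name
        self.evalue = evalue
        self.source = source
        self.metadata = dict(metadata) if metadata else {}

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))

    def __repr__(self) -> str:
        return (
            f"Motif({self.name!r}, w={self.width}, nsites={self.nsites:g}, "
            f"consensus={self.consensus})"
        )


@dataclass(frozen=True)
class MotifHit:
    """A stranded genomic motif occurrence above a log-odds threshold."""

    motif_name: str
    interval: GenomicInterval
    strand: str
    llr_score: float


def pfm_to_pwm(
    motif: Motif, background: Optional[np.ndarray] = None, pseudocount: float = 1.0
) -> np.ndarray:
    """log2-odds matrix: log2(((c + pc*bg) / (nsites + pc)) / bg)."""
    bg = uniform_background() if background is None else np.asarray(background)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")
    if np.any(bg <= 0):
        raise ValueError("background entries must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    probs = (motif.counts + pseudocount * bg[:, None]) / (motif.nsites + pseudocount)
    return np.log2(probs / bg[:, None])


def information_content(
    motif: Motif, background: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """Total and per-column information content in bits (no pseudocount)."""
    bg = uniform_background() if background is None else np.asarray(background)
    if np.any(bg <= 0):
        raise ValueError("background entries must be positive")
    p = motif.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg[:, None]), 0.0)
    per_column = terms.sum(axis=0)
    return float(per_column.sum()), per_column


def reverse_complement_motif(motif: Motif) -> Motif:
    rc = motif.counts[::-1, ::-1].copy()
    return Motif(
        counts=rc,
        nsites=motif.nsites,
        name=motif.name,
        evalue=motif.evalue,
        source=motif.source,
        metadata=motif.metadata,
    )


def _column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation per aligned column pair; constant columns give 0."""
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    num = (ac * bc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return corr


def _best_alignment(
    p1: np.ndarray, p2: np.ndarray
) -> Tuple[float, int]:
    """Best (overlap-weighted mean column correlation, offset) of p2 slid
    along p1.

    Offset is the position of p2's first column relative to p1's first.
    Scores are weighted by overlap / min(w1, w2): unrelated motifs sharing a
    short lucky overlap must not look similar, while a complete match of the
    shorter motif keeps its plain mean correlation.
    """
    w1, w2 = p1.shape[1], p2.shape[1]
    best, best_offset = -np.inf, 0
    for offset in range(-(w2 - MIN_OVERLAP), w1 - MIN_OVERLAP + 1):
        lo1, hi1 = max(0, offset), min(w1, offset + w2)
        overlap = hi1 - lo1
        if overlap < MIN_OVERLAP:
            continue
        cols1 = p1[:, lo1:hi1]
        cols2 = p2[:, lo1 - offset : hi1 - offset]
        weight = overlap / min(w1, w2)
        score = float(_column_correlations(cols1, cols2).mean()) * weight
        if score > best:
            best, best_offset = score, offset
    return best, best_offset


def _best_alignment_rc_aware(
    m1: Motif, m2: Motif
) -> Tuple[float, int, bool]:
    """Best alignment of m2 (or RC(m2)) against m1: (corr, offset, is_rc)."""
    p1 = m1.probabilities
    fwd, off_f = _best_alignment(p1, m2.probabilities)
    rev, off_r = _best_alignment(p1, reverse_complement_motif(m2).probabilities)
    if rev > fwd:
        return rev, off_r, True
    return fwd, off_f, False


def motif_distance(m1: Motif, m2: Motif) -> float:
    """Similarity distance in [0, 1]; 0 for identical (or RC) motifs."""
    corr, _, _ = _best_alignment_rc_aware(m1, m2)
    return float(min(1.0, max(0.0, 1.0 - corr)))


def _connected_components(n: int, edges: List[Tuple[int, int]]) -> List[List[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def cluster_and_merge(
    motifs: Sequence[Motif], threshold: float = 0.4
) -> List[Motif]:
    """Single-linkage clustering at ``distance < threshold``; merge clusters.

    Members are aligned (RC-aware) to the cluster's highest-nsites member and
    their counts summed over the shared span; trailing non-overlapping columns
    are trimmed. Total nsites is conserved. Output is ordered by decreasing
    nsites, ties broken by name.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    motifs = list(motifs)
    if not motifs:
        return []
    n = len(motifs)
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if motif_distance(motifs[i], motifs[j]) < threshold
    ]
    merged: List[Motif] = []
    for comp in _connected_components(n, edges):
        members = sorted(comp, key=lambda i: (-motifs[i].nsites, motifs[i].name))
        if len(members) == 1:
            merged.append(motifs[members[0]])
            continue
        ref = motifs[members[0]]
        counts = ref.counts.copy()
        nsites = ref.nsites
        names = [ref.name]
        current = Motif(counts=counts, nsites=nsites, name=ref.name)
        for idx in members[1:]:
            m = motifs[idx]
            _, offset, is_rc = _best_alignment_rc_aware(current, m)
            other = reverse_complement_motif(m) if is_rc else m
            lo = max(0, offset)
            hi = min(current.width, offset + other.width)
            span = current.counts[:, lo:hi] + other.counts[:, lo - offset : hi - offset]
            nsites = current.nsites + other.nsites
            names.append(m.name)
            current = Motif(counts=span, nsites=nsites, name="+".join(names))
        current.source = "merged"
        merged.append(current)
    merged.sort(key=lambda m: (-m.nsites, m.name))
    return merged


def motif_report(
    motifs: Sequence[Motif], background: Optional[np.ndarray] = None
) -> str:
    """Tab-separated per-motif summary (consensus, width, IC, nsites, e-value)."""
    lines = ["name\tconsensus\twidth\tic_bits\tnsites\tevalue"]
    for m in motifs:
        total_ic, _ = information_content(m, background)
        ev = "" if m.evalue is None else f"{m.evalue:.3g}"
        lines.append(
            f"{m.name}\t{m.consensus}\t{m.width}\t{total_ic:.3f}\t{m.nsites:g}\t{ev}"
        )
    return "\n".join(lines) + "\n"
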