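"""Synthetic genomes, implanted motif sites and footprint-shaped score
tracks, so the whole pipeline is testable without external data.

Tracks carry a flat-topped bump of fixed height over each implanted site
(site span plus a plateau pad) with truncated-Gaussian noise elsewhere. All
generators are deterministic given their seed, and truth is exportable as
BED + JASPAR text so downstream consumers only see standard formats.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import (
    GenomicInterval,
    ScoreTrack,
    reverse_complement,
    write_bed,
    write_motifs,
)
from .motif_model import BASES, Motif

__all__ = [
    "TruthSite",
    "SyntheticTruth",
    "make_genome",
    "implant_motifs",
    "make_fp_track",
    "make_two_condition_tracks",
    "write_truth",
]


@dataclass(frozen=True)
class TruthSite:
    interval: GenomicInterval
    strand: str
    motif_name: str


@dataclass
class SyntheticTruth:
    motifs: List[Motif]
    sites: List[TruthSite]
    track_params: Dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0


def make_genome(
    length: int,
    gc_fraction: float = 0.5,
    rng_seed: int = 0,
    name: str = "chr1",
) -> Dict[str, str]:
    """Random genome with i.i.d. bases, P(G) = P(C) = gc_fraction / 2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return {name: "".join(bases)}


def _sample_site(pfm: Motif, rng: np.random.Generator) -> str:
    probs = pfm.probabilities
    return "".join(
        BASES[rng.choice(4, p=probs[:, j])] for j in range(pfm.width)
    )


def implant_motifs(
    genome: Mapping[str, str],
    pfms: Sequence[Motif],
    counts: Optional[Sequence[int]] = None,
    ratios: Optional[Sequence[float]] = None,
    total_sites: Optional[int] = None,
    rng_seed: int = 0,
    min_gap: int = 10,
    max_retry_factor: int = 200,
) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Implant motif instances at non-overlapping random locations.

    Provide either absolute ``counts`` per motif or ``ratios`` together with
    ``total_sites`` (e.g. ratios (0.4, 0.3, 0.2, 0.1) of 2000 sites). Site
    sequences are sampled per-column from each PFM and placed uniformly on a
    random strand, at least ``min_gap`` bp apart. Placement failure after
    bounded retries is an error.
    """
    if counts is None:
        if ratios is None or total_sites is None:
            raise ValueError("provide counts, or ratios with total_sites")
        counts = [int(round(r * total_sites)) for r in ratios]
    if len(counts) != len(pfms):
        raise ValueError("one count per motif required")

    rng = np.random.default_rng(rng_seed)
    chroms = sorted(genome)
    seqs = {c: list(genome[c]) for c in chroms}
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()
    occupied = {c: np.zeros(len(genome[c]), dtype=bool) for c in chroms}

    sites: List[TruthSite] = []
    total = int(sum(counts))
    retries_left = max_retry_factor * max(total, 1)
    for pfm, count in zip(pfms, counts):
        w = pfm.width
        placed = 0
        while placed < count:
            if retries_left <= 0:
                raise RuntimeError(
                    f"could not place {total} non-overlapping sites; genome too small"
                )
            retries_left -= 1
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = len(genome[chrom])
            if L < w + 2 * min_gap:
                continue
            pos = int(rng.integers(min_gap, L - w - min_gap + 1))
            lo, hi = max(0, pos - min_gap), min(L, pos + w + min_gap)
            if occupied[chrom][lo:hi].any():
                continue
            occupied[chrom][lo:hi] = True
            strand = "+" if rng.random() < 0.5 else "-"
            site_seq = _sample_site(pfm, rng)
            inserted = site_seq if strand == "+" else reverse_complement(site_seq)
            seqs[chrom][pos : pos + w] = list(inserted)
            sites.append(
                TruthSite(GenomicInterval(chrom, pos, pos + w), strand, pfm.name)
            )
            placed += 1

    new_genome = {c: "".join(seqs[c]) for c in chroms}
    truth = SyntheticTruth(
        motifs=[copy.deepcopy(m) for m in pfms],
        sites=sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start)),
        rng_seed=rng_seed,
    )
    return new_genome, truth


def make_fp_track(
    chrom_lengths: Mapping[str, int],
    sites: Sequence[TruthSite],
    peak_height: float = 1.0,
    plateau_pad: int = 5,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> ScoreTrack:
    """Flat-topped bump of ``peak_height`` over each site +/- ``plateau_pad``;
    truncated-at-zero Gaussian noise elsewhere."""
    rng = np.random.default_rng(rng_seed)
    data = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if noise_sd > 0:
            vec = np.clip(rng.normal(0.0, noise_sd, size=length), 0.0, None)
        else:
            vec = np.zeros(length)
        data[chrom] = vec
    for site in sites:
        iv = site.interval
        if iv.chrom not in data:
            continue
        lo = max(0, iv.start - plateau_pad)
        hi = min(len(data[iv.chrom]), iv.end + plateau_pad)
        data[iv.chrom][lo:hi] = peak_height
    return ScoreTrack(data)


def make_two_condition_tracks(
    chrom_lengths: Mapping[str, int],
    shared_sites: Sequence[TruthSite],
    exclusive_sites: Sequence[TruthSite],
    peak_height: float = 1.0,
    plateau_pad: int = 5,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> Tuple[ScoreTrack, ScoreTrack]:
    """Condition A carries shared + exclusive bumps, condition B shared only,
    so the differential track A - B has bumps exactly at the exclusive sites
    in the noise-free case."""
    track_a = make_fp_track(
        chrom_lengths,
        list(shared_sites) + list(exclusive_sites),
        peak_height,
        plateau_pad,
        noise_sd,
        rng_seed,
    )
    track_b = make_fp_track(
        chrom_lengths, shared_sites, peak_height, plateau_pad, noise_sd, rng_seed + 1
    )
    return track_a, track_b


def write_truth(truth: SyntheticTruth, sites_bed: str, motifs_jaspar: str) -> None:
    intervals = [
        GenomicInterval(s.interval.chrom, s.interval.start, s.interval.end, s.strand)
        for s in truth.sites
    ]
    names = [s.motif_name for s in truth.sites]
    write_bed(intervals, sites_bed, names=names)
    write_motifs(truth.motifs, motifs_jaspar, format="jaspar")
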