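"""Iterative de novo motif generation from footprint sequences.

Each iteration seeds a zero-or-one-occurrence-per-sequence (ZOOPS) EM finder
with overrepresented k-mers, scores the resulting motifs with a binomial
e-value, selects significant motifs with a knee-point filter, and removes the
exact motif locations from the sequence pool while retaining the flanks.
Iteration stops when the pool is exhausted, a maximum iteration count is
reached, or several consecutive iterations produce no significant motif.
All significant motifs are finally clustered and merged into consensus
motifs.

The finder is pluggable: any callable with the :func:`em_zoops` signature
(e.g. an adapter around an external motif discovery binary that reads a
FASTA pool and emits MEME-minimal motifs) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .footprints import Footprint
from .io_formats import GenomicInterval, reverse_complement
from .motif_model import (
    Motif,
    background_from_sequences,
    cluster_and_merge,
    motif_distance,
    pfm_to_pwm,
)
from .masking import encode_sequence

__all__ = [
    "PoolSequence",
    "DiscoveryParams",
    "IterationRecord",
    "DiscoveryResult",
    "seed_kmers",
    "em_zoops",
    "motif_evalue",
    "overfit_corrected_evalue",
    "knee_filter",
    "subtract_sites",
    "iterative_discovery",
]

_NEG = -1.0e30  # stand-in for -inf that survives arithmetic


@dataclass(frozen=True)
class PoolSequence:
    """A pool member: a footprint (fragment) sequence with genomic coordinates."""

    chrom: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")


@dataclass
class DiscoveryParams:
    motif_width_range: Tuple[int, int] = (6, 15)
    seeds_per_iteration: int = 3
    motifs_per_iteration: int = 3
    max_iterations: int = 30
    stagnation_limit: int = 3
    evalue_cap: float = 0.05
    merge_threshold: float = 0.4
    min_fragment_size: int = 6
    rng_seed: int = 0
    em_max_iter: int = 100
    em_tol: float = 1e-3

    def __post_init__(self) -> None:
        w_min, w_max = self.motif_width_range
        if not (4 <= w_min <= w_max):
            raise ValueError("require 4 <= w_min <= w_max")
        if self.stagnation_limit < 1:
            raise ValueError("stagnation_limit must be >= 1")


@dataclass
class IterationRecord:
    index: int
    motifs: List[Motif]
    significant: List[bool]
    pool_size_before: int


@dataclass
class DiscoveryResult:
    iterations: List[IterationRecord]
    consensus: List[Motif]
    sites: Dict[str, List[Tuple[GenomicInterval, str]]]
    pool_sizes: List[int]  # sequence counts per iteration boundary
    pool_bps: List[int] = field(default_factory=list)  # total bp, strictly decreasing on progress

    @property
    def significant_motifs(self) -> List[Motif]:
        return [
            m
            for rec in self.iterations
            for m, sig in zip(rec.motifs, rec.significant)
            if sig
        ]


# ---------------------------------------------------------------------------
# seeding


def seed_kmers(sequences: Sequence[str], w: int, top_k: int) -> List[str]:
    """Top k-mers by z-score of the observed count against the pool's
    mononucleotide background.

    A k-mer and its reverse complement are collapsed into one class keyed by
    the lexicographically smaller member; counting the forward strand for
    both members is equivalent to counting the class on both strands.
    """
    counts: Dict[str, int] = {}
    n_windows = 0
    for seq in sequences:
        for j in range(len(seq) - w + 1):
            kmer = seq[j : j + w]
            if "N" in kmer:
                continue
            n_windows += 1
            rc = reverse_complement(kmer)
            counts[min(kmer, rc)] = counts.get(min(kmer, rc), 0) + 1
    if n_windows == 0:
        return []
    bg = background_from_sequences(sequences)
    base_p = {b: bg[i] for i, b in enumerate("ACGT")}

    def kmer_prob(kmer: str) -> float:
        p = 1.0
        for b in kmer:
            p *= base_p[b]
        return p

    scored = []
    for kmer, obs in counts.items():
        rc = reverse_complement(kmer)
        p_class = kmer_prob(kmer) + (kmer_prob(rc) if rc != kmer else 0.0)
        expected = n_windows * p_class
        sd = np.sqrt(max(expected * (1.0 - p_class), 1e-12))
        scored.append(((obs - expected) / sd, kmer))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [kmer for _, kmer in scored[:top_k]]


# ---------------------------------------------------------------------------
# ZOOPS EM


def _log_ratio_matrices(
    probs: np.ndarray, background: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """(5, w) forward and reverse-strand log P(base|col)/P(base|bg); the fifth
    row absorbs padding/N codes with an effectively -inf score."""
    w = probs.shape[1]
    lf = np.full((5, w), _NEG)
    lr = np.full((5, w), _NEG)
    logp = np.log(np.maximum(probs, 1e-300))
    logbg = np.log(background)
    lf[:4] = logp - logbg[:, None]
    lr[:4] = logp[::-1, ::-1] - logbg[:, None]
    return lf, lr


def em_zoops(
    sequences: Sequence[str],
    seed: str,
    w: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-3,
    rng_seed: int = 0,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.1,
) -> Tuple[Optional[Motif], List[Tuple[int, int, str]]]:
    """Fit a ZOOPS motif model by EM, seeded from a k-mer.

    Each sequence holds zero or one motif occurrence on either strand. The
    E-step computes the posterior over (no site, site at offset j on strand
    s); the M-step re-estimates the PFM (pseudocount 0.1) and the
    site prior. Returns the motif built from the final hard assignments
    (maximum-posterior site where the site beats the no-site posterior,
    refined by a few hard-EM polish rounds) together with the assigned sites
    as ``(sequence index, offset, strand)``. Returns ``(None, [])`` when no
    sequence is assigned. Deterministic.
    """
    if w is None:
        w = len(seed)
    if len(seed) != w:
        raise ValueError("seed width must equal w")
    lengths = [len(s) for s in sequences]
    usable = [i for i, L in enumerate(lengths) if L >= w]
    if not usable:
        raise ValueError(f"no sequence of length >= {w}")

    if background is None:
        background = background_from_sequences(sequences)
    background = np.asarray(background, dtype=np.float64)

    max_len = max(lengths[i] for i in usable)
    n = len(usable)
    codes = np.full((n, max_len), 4, dtype=np.int8)
    for row, i in enumerate(usable):
        codes[row, : lengths[i]] = encode_sequence(sequences[i])
    n_offsets = np.array([lengths[i] - w + 1 for i in usable], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w, axis=1)
    karr = np.arange(w)

    # seed initialisation: dominant base at 0.7
    probs = np.full((4, w), 0.1)
    seed_codes = encode_sequence(seed)
    for j, b in enumerate(seed_codes):
        if b < 4:
            probs[b, j] = 0.7
    probs /= probs.sum(axis=0, keepdims=True)

    gamma = 0.5
    prev_ll = -np.inf
    for _ in range(max_iter):
        lf, lr = _log_ratio_matrices(probs, background)
        llr_f = lf[windows, karr].sum(axis=2)
        llr_r = lr[windows, karr].sum(axis=2)
        prior = gamma / (2.0 * n_offsets)[:, None]
        rf = prior * np.exp(np.minimum(llr_f, 500.0))
        rr = prior * np.exp(np.minimum(llr_r, 500.0))
        z = (1.0 - gamma) + rf.sum(axis=1) + rr.sum(axis=1)
        wf = rf / z[:, None]
        wr = rr / z[:, None]

        counts = np.zeros((5, w))
        np.add.at(counts, (windows, karr), wf[:, :, None])
        rc_windows = 3 - windows[:, :, ::-1]  # complement of reversed window
        np.add.at(counts, (np.where(rc_windows < 0, 4, rc_windows), karr), wr[:, :, None])
        new_probs = counts[:4] + pseudocount * background[:, None]
        new_probs /= new_probs.sum(axis=0, keepdims=True)

        site_post = (wf.sum(axis=1) + wr.sum(axis=1)).clip(0.0, 1.0)
        gamma = float(np.clip(site_post.mean(), 1e-4, 0.999))
        probs = new_probs

        ll = float(np.log(z).sum())
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll

    # hard assignment, followed by a few hard-EM polish rounds: reassign from
    # the hard-count matrix and re-estimate until stable. This sharpens fits
    # that soft EM left diluted across a mixed pool.
    sites: List[Tuple[int, int, str]] = []
    hard = np.zeros((4, w))
    prev_sites: Optional[List[Tuple[int, int, str]]] = None
    for _ in range(5):
        lf, lr = _log_ratio_matrices(probs, background)
        llr_f = lf[windows, karr].sum(axis=2)
        llr_r = lr[windows, karr].sum(axis=2)
        prior = gamma / (2.0 * n_offsets)[:, None]
        rf = prior * np.exp(np.minimum(llr_f, 500.0))
        rr = prior * np.exp(np.minimum(llr_r, 500.0))
        no_site = 1.0 - gamma

        sites = []
        hard = np.zeros((4, w))
        for row, i in enumerate(usable):
            jf = int(np.argmax(rf[row]))
            jr = int(np.argmax(rr[row]))
            if rf[row, jf] >= rr[row, jr]:
                best, j, strand = rf[row, jf], jf, "+"
            else:
                best, j, strand = rr[row, jr], jr, "-"
            if best <= no_site:
                continue
            sites.append((i, j, strand))
            window = codes[row, j : j + w]
            if strand == "+":
                hard[window, karr] += 1.0
            else:
                hard[3 - window[::-1], karr] += 1.0
        if not sites or sites == prev_sites:
            break
        prev_sites = sites
        probs = hard + pseudocount * background[:, None]
        probs /= probs.sum(axis=0, keepdims=True)
        gamma = float(np.clip(len(sites) / n, 1e-4, 0.999))

    if not sites:
        return None, []
    motif = Motif(counts=hard, nsites=float(len(sites)), name=f"em_{seed}")
    return motif, sites


# ---------------------------------------------------------------------------
# significance


def motif_evalue(
    motif: Motif,
    site_count: int,
    pool_size: int,
    background: np.ndarray,
    tests_performed: int,
    mean_length: float,
) -> float:
    """Binomial-tail e-value for observing ``site_count`` sites in the pool.

    The per-sequence null success probability is the chance that a background
    sequence of the pool's mean length contains a site matching at the
    motif's own information-content level:
    ``p0 = min(1, 2 (mean_length - w + 1) 2^(-IC_total))``.
    The tail P[X >= site_count] is multiplied by the number of motif fits
    performed and clamped to [0, tests_performed].
    """
    if site_count > pool_size:
        raise ValueError("site_count exceeds pool size")
    if site_count <= 0:
        return float(tests_performed)
    # IC regularized by one background-distributed pseudo-site: a motif fit to
    # very few sequences is near one-hot and would otherwise look arbitrarily
    # informative, making overfit singleton motifs spuriously significant
    probs = (motif.counts + background[:, None]) / (motif.nsites + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / background[:, None]), 0.0)
    ic_total = float(terms.sum())
    positions = max(mean_length - motif.width + 1.0, 1.0)
    p0 = min(1.0, 2.0 * positions * 2.0 ** (-ic_total))
    p = float(stats.binom.sf(site_count - 1, pool_size, p0))
    return float(np.clip(p * tests_performed, 0.0, tests_performed))


def _log2comb(n: float, k: float) -> float:
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(2))


def _binom_log10_evalue(
    motif: Motif,
    site_count: int,
    pool_size: int,
    background: np.ndarray,
    tests_performed: int,
    mean_length: float,
) -> float:
    """log10 of the binomial e-value, without underflow clamping."""
    if site_count <= 0:
        return float(np.log10(tests_performed))
    probs = (motif.counts + background[:, None]) / (motif.nsites + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / background[:, None]), 0.0)
    ic_total = float(terms.sum())
    positions = max(mean_length - motif.width + 1.0, 1.0)
    p0 = min(1.0, 2.0 * positions * 2.0 ** (-ic_total))
    log_p = float(stats.binom.logsf(site_count - 1, pool_size, p0))
    return min(log_p / np.log(10) + np.log10(tests_performed),
               float(np.log10(tests_performed)))


def _description_net_bits(
    motif: Motif,
    sites: Sequence[Tuple[int, int, str]],
    sequences: Sequence[str],
    background: np.ndarray,
) -> float:
    """Summed site log2-odds minus selection and parameter costs (see
    :func:`overfit_corrected_evalue`)."""
    k = len(sites)
    w = motif.width
    pwm = pfm_to_pwm(motif, background, pseudocount=1.0)
    padded = np.vstack([pwm, np.full((1, w), -np.inf)])
    total_bits = 0.0
    for i, j, strand in sites:
        codes = encode_sequence(sequences[i][j : j + w])
        if strand == "-":
            codes = (3 - codes)[::-1]
            codes[codes < 0] = 4
        total_bits += float(padded[codes, np.arange(w)].sum())
    n_windows = sum(2 * max(len(s) - w + 1, 0) for s in sequences)
    selection_bits = _log2comb(n_windows, k)
    parameter_bits = 0.75 * w * np.log2(k + 1)
    return total_bits - selection_bits - parameter_bits


def overfit_corrected_evalue(
    motif: Motif,
    sites: Sequence[Tuple[int, int, str]],
    sequences: Sequence[str],
    background: np.ndarray,
    tests_performed: int,
) -> float:
    """Description-length e-value guarding against EM overfitting.

    The motif's evidence is the summed per-site log2-odds of its assigned
    windows against the background. Because EM both selects the windows (k of
    all candidate windows, both strands) and fits the matrix to them, the
    evidence is discounted by the selection cost log2 C(windows, k) and a
    BIC-like parameter cost; the remainder is converted to an e-value. A
    motif re-described from its own noise scores near zero net bits and is
    rejected, while genuinely shared patterns keep hundreds of net bits.
    """
    if len(sites) == 0:
        return float(tests_performed)
    net = _description_net_bits(motif, sites, sequences, background)
    if net > 1000.0:
        return 0.0
    return float(np.clip(tests_performed * 2.0 ** (-net), 0.0, tests_performed))


def knee_filter(evalues: Sequence[float], evalue_cap: float = 0.05) -> List[int]:
    """Indices of significant motifs via a Kneedle-style knee on -log10(E).

    Values are sorted descending, min-max normalized, and the knee is the
    point of maximum distance to the chord from the first to the last point.
    Motifs strictly before the knee with E <= cap are significant. With fewer
    than three motifs (or a flat curve) the cap alone decides.
    """
    if len(evalues) == 0:
        raise ValueError("need at least one e-value")
    e = np.asarray(evalues, dtype=np.float64)
    s = -np.log10(np.maximum(e, 1e-300))
    if len(e) < 3 or np.isclose(s.max(), s.min()):
        return [int(i) for i in np.flatnonzero(e <= evalue_cap)]
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    x = np.linspace(0.0, 1.0, len(s_sorted))
    y = (s_sorted - s_sorted.min()) / (s_sorted.max() - s_sorted.min())
    chord_dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    knee = int(np.argmax(chord_dist))
    significant = [int(order[pos]) for pos in range(knee) if e[order[pos]] <= evalue_cap]
    return sorted(significant)


# ---------------------------------------------------------------------------
# pool subtraction


def subtract_sites(
    pool: Sequence[PoolSequence],
    sites: Sequence[Tuple[int, int, int]],
    min_fragment_size: int,
) -> List[PoolSequence]:
    """Remove site spans ``(pool index, start offset, end offset)`` from pool
    sequences; flanking fragments of at least ``min_fragment_size`` bp re-enter
    the pool with updated genomic coordinates."""
    blocks: Dict[int, List[Tuple[int, int]]] = {}
    for idx, s, e in sites:
        if not (0 <= idx < len(pool)):
            raise IndexError(f"site references unknown pool member {idx}")
        seq_len = len(pool[idx].seq)
        if not (0 <= s < e <= seq_len):
            raise ValueError(f"site [{s},{e}) outside sequence of length {seq_len}")
        blocks.setdefault(idx, []).append((s, e))

    out: List[PoolSequence] = []
    for idx, ps in enumerate(pool):
        if idx not in blocks:
            out.append(ps)
            continue
        merged = []
        for s, e in sorted(blocks[idx]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cursor = 0
        for s, e in merged:
            if s - cursor >= min_fragment_size:
                out.append(
                    PoolSequence(
                        ps.chrom, ps.start + cursor, ps.start + s, ps.seq[cursor:s]
                    )
                )
            cursor = e
        if len(ps.seq) - cursor >= min_fragment_size:
            out.append(
                PoolSequence(
                    ps.chrom, ps.start + cursor, ps.end, ps.seq[cursor:]
                )
            )
    return out


# ---------------------------------------------------------------------------
# the iterative loop


def build_pool(
    fps: Sequence[Footprint], genome: Dict[str, str]
) -> List[PoolSequence]:
    """Footprint sequences (plus strand); sequences containing N are dropped."""
    pool = []
    for fp in fps:
        iv = fp.interval
        seq = genome[iv.chrom][iv.start : iv.end]
        if "N" in seq:
            continue
        pool.append(PoolSequence(iv.chrom, iv.start, iv.end, seq))
    return pool


def iterative_discovery(
    fps: Sequence[Footprint],
    genome: Dict[str, str],
    params: Optional[DiscoveryParams] = None,
    finder: Optional[Callable] = None,
) -> DiscoveryResult:
    """Run the iterative discovery loop on footprint sequences."""
    if not fps:
        raise ValueError("empty footprint list")
    params = params or DiscoveryParams()
    finder = finder or em_zoops
    w_min, w_max = params.motif_width_range

    pool = build_pool(fps, genome)
    pool_sizes = [len(pool)]
    pool_bps = [sum(len(ps.seq) for ps in pool)]
    iterations: List[IterationRecord] = []
    site_map: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    all_significant: List[Motif] = []
    stagnation = 0

    for it in range(params.max_iterations):
        if not pool:
            break
        seqs = [ps.seq for ps in pool]
        background = background_from_sequences(seqs)
        mean_length = float(np.mean([len(s) for s in seqs]))
        tests = (w_max - w_min + 1) * params.seeds_per_iteration

        candidates = []  # (evalue, name, motif, sites)
        # after a stagnant iteration the pool is unchanged, so repeating the
        # same seeds would repeat the same outcome; explore deeper seed ranks
        seed_offset = stagnation * params.seeds_per_iteration
        for w in range(w_min, w_max + 1):
            ranked = seed_kmers(seqs, w, seed_offset + params.seeds_per_iteration)
            for seed in ranked[seed_offset:]:
                motif, sites = finder(
                    seqs,
                    seed,
                    w,
                    max_iter=params.em_max_iter,
                    tol=params.em_tol,
                    rng_seed=params.rng_seed,
                    background=background,
                )
                if motif is None:
                    continue
                # both significance gates, combined in log space so that
                # extremely significant motifs still rank strictly
                log10_e = max(
                    _binom_log10_evalue(
                        motif, len(sites), len(pool), background, tests, mean_length
                    ),
                    np.log10(tests)
                    - _description_net_bits(motif, sites, seqs, background)
                    * np.log10(2.0),
                )
                motif.evalue = float(
                    np.clip(10.0 ** max(log10_e, -300.0), 0.0, tests)
                )
                motif.name = f"iter{it}_w{w}_{seed}"
                motif.source = f"iteration={it}"
                candidates.append((log10_e, motif.name, motif, sites))

        if not candidates:
            stagnation += 1
            iterations.append(IterationRecord(it, [], [], len(pool)))
            pool_sizes.append(len(pool))
            pool_bps.append(pool_bps[-1])
            if stagnation >= params.stagnation_limit:
                break
            continue

        candidates.sort(key=lambda t: (t[0], t[1]))
        # drop near-duplicates of better-ranked candidates: their sites are
        # largely shared and a diluted blend must not shadow a pure fit
        deduped = []
        for cand in candidates:
            if all(
                motif_distance(cand[2], kept[2]) >= params.merge_threshold
                for kept in deduped
            ):
                deduped.append(cand)
        kept = deduped[: params.motifs_per_iteration]
        sig_idx = set(
            knee_filter([c[2].evalue for c in kept], params.evalue_cap)
        )
        flags = [i in sig_idx for i in range(len(kept))]
        iterations.append(
            IterationRecord(it, [c[2] for c in kept], flags, len(pool))
        )

        if not sig_idx:
            stagnation += 1
            pool_sizes.append(len(pool))
            pool_bps.append(pool_bps[-1])
            if stagnation >= params.stagnation_limit:
                break
            continue
        stagnation = 0

        spans: List[Tuple[int, int, int]] = []
        for i in sig_idx:
            _, _, motif, sites = kept[i]
            all_significant.append(motif)
            genomic = []
            for seq_idx, off, strand in sites:
                ps = pool[seq_idx]
                genomic.append(
                    (
                        GenomicInterval(
                            ps.chrom, ps.start + off, ps.start + off + motif.width
                        ),
                        strand,
                    )
                )
                spans.append((seq_idx, off, off + motif.width))
            site_map[motif.name] = genomic

        pool = subtract_sites(pool, spans, params.min_fragment_size)
        pool_sizes.append(len(pool))
        pool_bps.append(sum(len(ps.seq) for ps in pool))

    consensus = cluster_and_merge(all_significant, params.merge_threshold)
    return DiscoveryResult(
        iterations=iterations,
        consensus=consensus,
        sites=site_map,
        pool_sizes=pool_sizes,
        pool_bps=pool_bps,
    )
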