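"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open (BED convention). GTF/GFF input is
converted on read. Score tracks are dense per-base float vectors, one per
chromosome; bedGraph is the canonical text dialect, BigWig is supported when
``pyBigWig`` is importable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "ScoreTrack",
    "Feature",
    "FormatError",
    "read_score_track",
    "write_score_track",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_sequences",
    "read_bed",
    "write_bed",
    "read_motifs",
    "write_motifs",
    "read_gtf_features",
    "read_gene_sets",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Feature:
    """A named genomic feature (e.g. a gene) from GTF/GFF."""

    interval: GenomicInterval
    name: str


class ScoreTrack:
    """Per-chromosome dense vectors of non-negative per-base scores."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self._data: Dict[str, np.ndarray] = {}
        for chrom, vec in data.items():
            arr = np.asarray(vec, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: score vector must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite score")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative score")
            self._data[chrom] = arr

    @property
    def chroms(self) -> List[str]:
        return list(self._data)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self._data.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        return self.lengths == other.lengths and all(
            np.array_equal(self._data[c], other._data[c]) for c in self._data
        )

    def items(self) -> Iterable[Tuple[str, np.ndarray]]:
        return self._data.items()


# ---------------------------------------------------------------------------
# score tracks


def read_score_track(
    path: str,
    dialect: str = "bedgraph",
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> ScoreTrack:
    """Read a per-base score track from bedGraph or BigWig.

    For bedGraph, chromosome lengths default to the maximal end coordinate
    seen per chromosome; pass ``chrom_lengths`` to pad beyond that.
    Overlapping bedGraph records are a validation error.
    """
    if dialect == "bedgraph":
        return _read_bedgraph(path, chrom_lengths)
    if dialect == "bigwig":
        return _read_bigwig(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bedgraph(
    path: str, chrom_lengths: Optional[Mapping[str, int]]
) -> ScoreTrack:
    records: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            records.setdefault(chrom, []).append((start, end, value))

    data: Dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        prev_end = 0
        for start, end, _ in recs:
            if start < prev_end:
                raise FormatError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            prev_end = end
        length = recs[-1][1]
        if chrom_lengths is not None:
            declared = chrom_lengths.get(chrom)
            if declared is not None:
                if declared < length:
                    raise FormatError(
                        f"{path}: record on {chrom} exceeds declared length {declared}"
                    )
                length = declared
        vec = np.zeros(length, dtype=np.float64)
        for start, end, value in recs:
            vec[start:end] = value
        data[chrom] = vec
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            data.setdefault(chrom, np.zeros(length, dtype=np.float64))
    return ScoreTrack(data)


def _read_bigwig(path: str) -> ScoreTrack:
    try:
        import pyBigWig  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "BigWig support requires the optional pyBigWig dependency; "
            "use the bedGraph dialect instead"
        ) from exc
    bw = pyBigWig.open(path)
    try:
        data = {}
        for chrom, length in bw.chroms().items():
            vec = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, length), dtype=np.float64)
            )
            data[chrom] = vec
        return ScoreTrack(data)
    finally:
        bw.close()


def write_score_track(track: ScoreTrack, path: str, dialect: str = "bedgraph") -> None:
    """Write a track; zero runs are omitted (bedGraph) for compactness."""
    if dialect == "bedgraph":
        with open(path, "w") as fh:
            for chrom, vec in track.items():
                for start, end, value in _constant_runs(vec):
                    if value != 0.0:
                        fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
    elif dialect == "bigwig":
        try:
            import pyBigWig  # type: ignore
        except ImportError as exc:  # pragma: no cover
            raise ImportError("BigWig support requires pyBigWig") from exc
        bw = pyBigWig.open(path, "w")
        bw.addHeader([(c, len(v)) for c, v in track.items()])
        for chrom, vec in track.items():
            starts, ends, values = [], [], []
            for start, end, value in _constant_runs(vec):
                if value != 0.0:
                    starts.append(start)
                    ends.append(end)
                    values.append(value)
            if starts:
                bw.addEntries(
                    [chrom] * len(starts), starts, ends=ends, values=values
                )
        bw.close()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _constant_runs(vec: np.ndarray) -> Iterable[Tuple[int, int, float]]:
    if len(vec) == 0:
        return
    change = np.flatnonzero(np.diff(vec)) + 1
    bounds = np.concatenate(([0], change, [len(vec)]))
    for i in range(len(bounds) - 1):
        yield int(bounds[i]), int(bounds[i + 1]), float(vec[bounds[i]])


# ---------------------------------------------------------------------------
# FASTA

_VALID_BASES = frozenset("ACGTN")


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    The name is the first whitespace-delimited token of the header.
    Duplicate names and characters outside {A,C,G,T,N} are errors.
    """
    genome: Dict[str, str] = {}
    name: Optional[str] = None
    chunks: List[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"{path}: invalid characters {sorted(bad)} in {name!r}")
        genome[name] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in genome:
                    raise FormatError(f"{path}:{lineno}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                chunks.append(line)
    _flush()
    return genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequences(
    genome: Mapping[str, str], intervals: Sequence[GenomicInterval]
) -> List[str]:
    """Extract interval sequences; minus-strand intervals reverse-complemented."""
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        out.append(reverse_complement(sub) if iv.strand == "-" else sub)
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3+ into intervals; strand taken from column 6 when present."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            out.append(GenomicInterval(parts[0], start, end, strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write BED3 (or BED6 when any name/score/strand is present)."""
    six = names is not None or scores is not None or any(
        iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else str(i)
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# motifs (JASPAR / MEME minimal)

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([0-9.\seEe+-]*?)\s*\]?\s*$")


def read_motifs(path: str, format: str = "jaspar"):
    from .motif_model import Motif  # deferred: avoid import cycle

    if format == "jaspar":
        return _read_jaspar(path, Motif)
    if format == "meme_minimal":
        return _read_meme_minimal(path, Motif)
    raise ValueError(f"unknown motif format {format!r}")


def _read_jaspar(path: str, Motif):
    """JASPAR PFM text. Header tokens of the form key=value (e.g. ``class=``)
    are stored as motif metadata."""
    motifs = []
    name = None
    meta: Dict[str, str] = {}
    rows: Dict[str, List[float]] = {}

    def _flush(lineno: int) -> None:
        nonlocal rows, meta
        if name is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(
                f"{path}:{lineno}: motif {name!r} needs exactly rows A,C,G,T "
                f"(got {sorted(rows)})"
            )
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise FormatError(f"{path}:{lineno}: row width mismatch in {name!r}")
        counts = np.array([rows[b] for b in "ACGT"], dtype=np.float64)
        motifs.append(Motif(counts=counts, name=name, metadata=dict(meta)))
        rows, meta = {}, {}

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                tokens = line[1:].split()
                if not tokens:
                    raise FormatError(f"{path}:{lineno}: empty motif header")
                plain = [t for t in tokens if "=" not in t]
                name = " ".join(plain) if plain else tokens[0]
                meta = dict(t.split("=", 1) for t in tokens if "=" in t)
            else:
                m = _JASPAR_ROW.match(line)
                if m is None or name is None:
                    raise FormatError(f"{path}:{lineno}: unparseable JASPAR line")
                base, values = m.group(1), m.group(2).split()
                if base in rows:
                    raise FormatError(f"{path}:{lineno}: duplicate row {base}")
                rows[base] = [float(v) for v in values]
        _flush(lineno)
    return motifs


def _read_meme_minimal(path: str, Motif):
    motifs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            name = tokens[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name!r} has no matrix")
                i += 1
            if i == len(lines):
                raise FormatError(f"{path}: motif {name!r} has no matrix")
            header = lines[i].strip()
            attrs = dict(re.findall(r"(\w+)=\s*([^\s]+)", header))
            w = int(attrs.get("w", 0))
            nsites = float(attrs.get("nsites", 20))
            evalue = float(attrs.get("E", 0)) if "E" in attrs else None
            i += 1
            probs = []
            while i < len(lines) and len(probs) < w:
                row = lines[i].split()
                if len(row) != 4:
                    raise FormatError(
                        f"{path}: matrix row with {len(row)} columns (need 4)"
                    )
                probs.append([float(v) for v in row])
                i += 1
            if len(probs) != w:
                raise FormatError(f"{path}: motif {name!r}: expected {w} rows")
            counts = np.array(probs, dtype=np.float64).T * nsites
            motifs.append(
                Motif(counts=counts, nsites=nsites, name=name, evalue=evalue)
            )
        else:
            i += 1
    return motifs


def write_motifs(motifs, path: str, format: str = "jaspar") -> None:
    if format == "jaspar":
        with open(path, "w") as fh:
            for m in motifs:
                header = f">{m.name}"
                for key, value in sorted(m.metadata.items()):
                    header += f" {key}={value}"
                fh.write(header + "\n")
                for bi, base in enumerate("ACGT"):
                    vals = " ".join(f"{v:.6g}" for v in m.counts[bi])
                    fh.write(f"{base} [ {vals} ]\n")
    elif format == "meme_minimal":
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write(
                "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            )
            for m in motifs:
                fh.write(f"MOTIF {m.name.replace(' ', '_')}\n")
                ev = m.evalue if m.evalue is not None else 0.0
                fh.write(
                    "letter-probability matrix: alength= 4 "
                    f"w= {m.width} nsites= {m.nsites:g} E= {ev:.3g}\n"
                )
                probs = m.probabilities
                for j in range(m.width):
                    fh.write(
                        " ".join(f"{probs[bi, j]:.6f}" for bi in range(4)) + "\n"
                    )
                fh.write("\n")
    else:
        raise ValueError(f"unknown motif format {format!r}")


# ---------------------------------------------------------------------------
# GTF/GFF and GMT

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')
_GFF_NAME = re.compile(r"(?:^|;)\s*(?:Name|ID|gene_id)=([^;]+)")


def read_gtf_features(
    path: str, feature_types: Iterable[str] = ("gene",)
) -> List[Feature]:
    """Read GTF/GFF3 features of the given types (1-based closed -> half-open)."""
    wanted = set(feature_types)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF/GFF columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype not in wanted:
                continue
            m = _GTF_GENE_ID.search(attrs) or _GFF_NAME.search(attrs)
            if m is None:
                raise FormatError(
                    f"{path}:{lineno}: no gene_id/Name/ID attribute found"
                )
            iv = GenomicInterval(
                chrom,
                int(start) - 1,
                int(end),
                strand if strand in "+-" else ".",
            )
            out.append(Feature(interval=iv, name=m.group(1).strip()))
    return out


def read_gene_sets(path: str) -> Dict[str, List[str]]:
    """Read GMT gene sets; the description column is dropped, genes deduplicated."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated columns"
                )
            name, genes = parts[0], parts[2:]
            seen: Dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g)
            sets[name] = list(seen)
    return sets
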