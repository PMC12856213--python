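"""Shared genomic data model and plain-text format I/O.

All coordinates are 0-based half-open (BED convention). Coverage tracks are
fixed-width bin vectors per chromosome; the trailing partial bin at a
chromosome end is dropped so every bin has the same width.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "PeakSet",
    "BinnedTrack",
    "TssTable",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "load_tss",
]

_ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class SequenceRecord:
    """An uppercase DNA sequence over {A,C,G,T,N} with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters in record {self.id!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded, named and scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """A labelled list of intervals kept sorted by (chrom, start, end).

    Intervals within one chromosome may overlap; operations that require
    merged input merge internally.
    """

    label: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def merged_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged (starts, ends) arrays for one chromosome.

        Overlapping or abutting intervals are coalesced, which preserves
        every >=1 bp intersection query.
        """
        ivs = self.by_chrom(chrom)
        if not ivs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        starts, ends = [], []
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = iv.start, iv.end
        starts.append(cur_s)
        ends.append(cur_e)
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


@dataclass
class BinnedTrack:
    """Fixed-bin, non-negative coverage vectors per chromosome.

    ``data[chrom]`` has length ``chrom_sizes[chrom] // bin_size`` — the
    trailing partial bin is dropped, keeping bin width constant.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            expected = self.chrom_sizes[chrom] // self.bin_size
            if len(vec) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"{chrom}: values must be finite and >= 0")
            self.data[chrom] = vec

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def concat(self) -> np.ndarray:
        """All bin values as one vector, chromosomes in sorted order."""
        return np.concatenate([self.data[c] for c in self.chroms()] or [np.empty(0)])

    def n_bins(self) -> int:
        return sum(len(v) for v in self.data.values())

    def scaled(self, factor: float) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_size,
            {c: v * factor for c, v in self.data.items()},
            dict(self.chrom_sizes),
        )


@dataclass
class TssTable:
    """Transcription start sites: (chrom, position, strand, gene_name) rows."""

    rows: list[tuple[str, int, str, str]]

    def __post_init__(self) -> None:
        for chrom, pos, strand, name in self.rows:
            if pos < 0:
                raise ValueError(f"negative TSS position for {name}")
            if strand not in ("+", "-"):
                raise ValueError(f"TSS {name}: strand must be + or -, got {strand!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, int, str, str]]:
        return iter(self.rows)


# ---------------------------------------------------------------------------
# FASTA


def _normalize_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = sorted(set(seq) - _ALPHABET)
    if bad:
        raise ValueError(
            f"record {record_id!r}: illegal characters {bad} "
            "(allowed: A, C, G, T, N)"
        )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized DNA records.

    Sequences are uppercased and U is mapped to T; any character outside
    {A,C,G,T,N} raises ``ValueError`` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read BED3+ into a PeakSet (0-based half-open, sorted).

    Column 6 is honoured as strand when present, otherwise '.'; column 4/5
    populate name/score when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return PeakSet(label or path.stem, intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6; round-trips with read_bed on (chrom, start, end, strand)."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = "0" if iv.score is None else f"{iv.score:g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph and chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_bedgraph(
    path: str | Path | io.TextIOBase,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
) -> BinnedTrack:
    """Regrid a 4-column bedGraph onto fixed bins.

    Each bin takes the coverage-weighted mean of overlapping segments, with
    uncovered bases contributing zero, so the integral over fully covered
    regions is conserved. Overlapping segments on one chromosome are an error.
    """
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh, close = path, False
    sums = {
        c: np.zeros(chrom_sizes[c] // bin_size, dtype=float) for c in chrom_sizes
    }
    last_end: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            if chrom not in chrom_sizes:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            start, end, value = int(s), int(e), float(v)
            if end <= start or start < 0:
                raise ValueError(f"line {lineno}: bad interval [{start},{end})")
            if start < last_end.get(chrom, 0):
                raise ValueError(
                    f"line {lineno}: overlapping segments on {chrom} "
                    "(bedGraph must be sorted and non-overlapping per chromosome)"
                )
            last_end[chrom] = end
            vec = sums[chrom]
            nbins = len(vec)
            b0 = start // bin_size
            b1 = min((end - 1) // bin_size, nbins - 1)
            for b in range(b0, b1 + 1):
                if b >= nbins:
                    break
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                if hi > lo:
                    vec[b] += value * (hi - lo)
    finally:
        if close:
            fh.close()
    data = {c: sums[c] / bin_size for c in sums}
    return BinnedTrack(bin_size, data, dict(chrom_sizes))


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write bin values as bedGraph, coalescing runs of equal value."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            run_start = 0
            for i in range(1, len(vec) + 1):
                if i == len(vec) or vec[i] != vec[run_start]:
                    fh.write(
                        f"{chrom}\t{run_start * track.bin_size}\t"
                        f"{i * track.bin_size}\t{vec[run_start]:g}\n"
                    )
                    run_start = i


# ---------------------------------------------------------------------------
# TSS tables


def load_tss(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> TssTable:
    """Load TSS positions from a BED-like gene table with a strand column.

    The TSS of a + gene is its start; of a − gene, end − 1 (the last base of
    the half-open interval). Rows without a strand column are an error.
    """
    rows: list[tuple[str, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: gene rows need 6 columns (strand missing)"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            if strand == "+":
                tss = start
            elif strand == "-":
                tss = end - 1
            else:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if chrom_sizes is not None and not (0 <= tss < chrom_sizes.get(chrom, tss + 1)):
                raise ValueError(f"{path}:{lineno}: TSS {tss} outside {chrom}")
            rows.append((chrom, tss, strand, name))
    return TssTable(rows)
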