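"""Synthetic benchmark generators with exact ground truth.

Every generator is seeded and bit-reproducible, and each emulates one class
of input the analysis consumes:

* ``make_genome`` — chromosomes of i.i.d. background sequence at a chosen GC
  with motifs drawn from a grammar planted at known, well-separated
  coordinates on random strands. Background segments are rejection-resampled
  until they contain no accidental hit of any planted class, and the 10 bp
  flanking each motif is A/T-only so planted tract structure can never chain
  into the background — the emitted truth intervals are therefore the
  *complete* hit set of the corresponding scanner.
* ``make_peak_pair`` — two peak sets with an exactly controlled fraction of
  A peaks overlapping B (disjoint slot construction).
* ``make_coverage`` — Poisson per-bin counts at a background rate, with a
  triangular enrichment kernel over peak intervals.
* ``make_titration`` — bound fractions from the quadratic isotherm plus
  additive Gaussian noise, clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formats import BinnedTrack, GenomicInterval, PeakSet, SequenceRecord
from .isotherm import TitrationSeries, bound_fraction
from .seqscan import PQS_CLASSES, revcomp, scan_c4, scan_pqs, scan_units

__all__ = [
    "SynthGenomeTruth",
    "SynthTrackTruth",
    "make_genome",
    "make_peak_pair",
    "make_coverage",
    "make_titration",
]

PLANTABLE_CLASSES = ("C4", "unit") + PQS_CLASSES

#: A/T-only background bases at every junction; exceeds the longest loop
#: (15 nt) plus tract length so no grammar can chain across a junction
_GUARD = 16
#: minimum background separation between planted motifs
_MIN_SEP = 20
#: background is rejection-sampled in blocks of at most this many bases
_BLOCK = 2000


@dataclass
class SynthGenomeTruth:
    genome: list[SequenceRecord]
    planted: PeakSet
    background_gc: float
    seed: int

    def chrom_sizes(self) -> dict[str, int]:
        return {rec.id: len(rec) for rec in self.genome}


@dataclass
class SynthTrackTruth:
    peaks: PeakSet
    enrichment: float
    background_rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must be > 1")
        if self.background_rate <= 0:
            raise ValueError("background rate must be > 0")


# ---------------------------------------------------------------------------
# motif sampling


def _sample_loop(rng: np.random.Generator, lo: int, hi: int) -> str:
    # loops are A/T-only so they can never extend or create a tract
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(["A", "T"], size=n))


def _sample_motif(rng: np.random.Generator, variant_class: str) -> str:
    """Draw one motif sequence from its grammar (tract lengths 3–5 unless
    the class dictates otherwise, loops 1–7 from {A,T})."""

    def tracts_and_loops(base: str, lens: list[int], loop_hi: int = 7) -> str:
        parts = [base * lens[0]]
        for L in lens[1:]:
            parts.append(_sample_loop(rng, 1, loop_hi))
            parts.append(base * L)
        return "".join(parts)

    tract_len = lambda: int(rng.integers(3, 6))
    if variant_class == "C4":
        return tracts_and_loops("C", [tract_len() for _ in range(4)])
    if variant_class == "unit":
        if rng.random() < 0.5:
            return "C" * int(rng.integers(7, 10))
        return tracts_and_loops("C", [tract_len(), tract_len()])
    if variant_class == "canonical4G":
        return tracts_and_loops("G", [tract_len() for _ in range(4)])
    if variant_class == "twoQuartet":
        # all tracts exactly GG, else the hit would be a higher class
        return tracts_and_loops("G", [2, 2, 2, 2])
    if variant_class == "GVBQ":
        lens = [tract_len() for _ in range(4)]
        lens[int(rng.integers(0, 4))] = 2
        return tracts_and_loops("G", lens)
    if variant_class == "longLoop15":
        lens = [tract_len() for _ in range(4)]
        seq = ["G" * lens[0]]
        long_at = int(rng.integers(0, 3))
        for i, L in enumerate(lens[1:]):
            lo, hi = (8, 15) if i == long_at else (1, 7)
            seq.append(_sample_loop(rng, lo, hi))
            seq.append("G" * L)
        return "".join(seq)
    if variant_class == "bulged":
        lens = [tract_len() for _ in range(4)]
        split_at = int(rng.integers(0, 4))
        parts = []
        for i, L in enumerate(lens):
            if i:
                parts.append(_sample_loop(rng, 1, 7))
            if i == split_at:
                a = int(rng.integers(1, L))
                parts.append("G" * a + _sample_loop(rng, 1, 3) + "G" * (L - a))
            else:
                parts.append("G" * L)
        return "".join(parts)
    raise ValueError(f"cannot plant class {variant_class!r}")


_SCANNERS = {
    "C4": lambda s: scan_c4(s, 4),
    "unit": scan_units,
    **{cls: (lambda s, c=cls: scan_pqs(s, c)) for cls in PQS_CLASSES},
}


def _has_hit(seq: str, classes: list[str]) -> bool:
    return any(_SCANNERS[c](seq) for c in classes)


def _sample_block(
    rng: np.random.Generator, n: int, gc: float, classes: list[str], max_tries: int = 200
) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    at = np.array(list("AT"))
    for _ in range(max_tries):
        arr = rng.choice(bases, size=n, p=p)
        g = min(_GUARD, n)
        arr[:g] = rng.choice(at, size=g)
        tail = min(_GUARD, n - g)
        if tail:
            arr[-tail:] = rng.choice(at, size=tail)
        seg = "".join(arr)
        if not _has_hit(seg, classes):
            return seg
    raise RuntimeError(
        f"could not draw a motif-free background block of {n} bp "
        f"in {max_tries} tries; lower gc"
    )


def _sample_background(
    rng: np.random.Generator, n: int, gc: float, classes: list[str]
) -> str:
    """An n-base background segment free of any hit of the given classes.

    Assembled from independently rejection-sampled blocks of <= ``_BLOCK``
    bases whose first/last ``_GUARD`` bases are A/T-only; since no grammar
    can span an A/T junction, per-block hit freedom implies segment-level
    hit freedom, and planted motifs can never chain into the background.
    """
    parts = []
    remaining = n
    while remaining > 0:
        m = min(_BLOCK, remaining)
        parts.append(_sample_block(rng, m, gc, classes))
        remaining -= m
    return "".join(parts)


def make_genome(
    n_chroms: int = 1,
    chrom_len: int = 1_000_000,
    n_motifs_per_class: dict[str, int] | None = None,
    gc: float = 0.41,
    seed: int = 0,
) -> SynthGenomeTruth:
    """Generate a genome with grammar-drawn motifs planted at known sites.

    Motifs of each requested class are drawn uniformly from their grammar,
    reverse-complemented onto the minus strand with probability 1/2, and
    placed non-overlapping with >= 20 bp of motif-free background between
    plants. The truth PeakSet records (span, strand, class) per plant and is
    exhaustive: scanning the emitted genome for a planted class returns
    exactly the truth intervals of that class — provided no *other* planted
    class subsumes it (e.g. a GVBQ plant also satisfies the twoQuartet
    grammar, and a canonical G4 plant is a C4 on the opposite strand); plant
    one class per genome when exact per-class recovery is required.
    """
    if n_motifs_per_class is None:
        n_motifs_per_class = {"C4": 50}
    for cls in n_motifs_per_class:
        if cls not in PLANTABLE_CLASSES:
            raise ValueError(f"cannot plant class {cls!r}")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = sorted(n_motifs_per_class)

    # round-robin class assignment, then shuffle placement order per chrom
    total = sum(n_motifs_per_class.values())
    per_chrom = [total // n_chroms + (1 if i < total % n_chroms else 0) for i in range(n_chroms)]
    assignment = [c for c in classes for _ in range(n_motifs_per_class[c])]
    rng.shuffle(assignment)

    records, truth = [], []
    pos_in_assignment = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        k = per_chrom[ci]
        motif_classes = assignment[pos_in_assignment : pos_in_assignment + k]
        pos_in_assignment += k
        motifs = []
        for cls in motif_classes:
            seq = _sample_motif(rng, cls)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seq if strand == "+" else revcomp(seq)
            motifs.append((cls, strand, placed))

        need = sum(len(m[2]) for m in motifs) + _MIN_SEP * (k + 1)
        if need > chrom_len:
            raise ValueError(
                f"{chrom}: cannot pack {k} motifs into {chrom_len} bp "
                f"with {_MIN_SEP} bp spacing (need >= {need})"
            )
        slack = chrom_len - need
        cuts = np.sort(rng.integers(0, slack + 1, size=k)) if k else np.empty(0, int)
        gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + _MIN_SEP

        parts, cursor = [], 0
        for (cls, strand, placed), gap in zip(motifs, gaps[:-1]):
            parts.append(_sample_background(rng, int(gap), gc, classes))
            cursor += int(gap)
            parts.append(placed)
            truth.append(
                GenomicInterval(chrom, cursor, cursor + len(placed), strand, cls)
            )
            cursor += len(placed)
        parts.append(_sample_background(rng, int(gaps[-1]), gc, classes))
        records.append(SequenceRecord(chrom, "".join(parts)))

    return SynthGenomeTruth(
        genome=records,
        planted=PeakSet("planted", truth),
        background_gc=gc,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# peak pairs with controlled overlap


def make_peak_pair(
    n_a: int,
    n_b: int,
    frac_overlap: float,
    chrom_sizes: dict[str, int],
    peak_len: int = 400,
    seed: int = 0,
) -> tuple[PeakSet, PeakSet]:
    """Two peak sets where exactly round(frac_overlap * n_a) A peaks
    intersect (>= 1 bp) some B peak and all other peaks are pairwise
    disjoint across sets.

    Construction: disjoint genomic slots are drawn; ``k`` slots hold an
    overlapping A/B pair (B placed, A shifted by a random offset that keeps
    >= 1 bp shared), the rest hold a lone A or lone B.
    """
    if not 0 <= frac_overlap <= 1:
        raise ValueError("frac_overlap must be in [0, 1]")
    if n_a < 1 or n_b < 1:
        raise ValueError("both sets must be non-empty")
    k = round(frac_overlap * n_a)
    if k > n_b:
        raise ValueError(
            f"need {k} overlapping pairs but only {n_b} B peaks available"
        )
    rng = np.random.default_rng(seed)
    slot_w = 4 * peak_len
    n_slots = k + (n_a - k) + (n_b - k)
    chroms = sorted(chrom_sizes)
    capacity = {c: chrom_sizes[c] // slot_w for c in chroms}
    if sum(capacity.values()) < n_slots:
        raise ValueError(
            f"genome too small: {n_slots} slots of {slot_w} bp needed"
        )

    # pick n_slots distinct slots across chromosomes, then shuffle roles
    all_slots = [(c, i) for c in chroms for i in range(capacity[c])]
    idx = rng.choice(len(all_slots), size=n_slots, replace=False)
    roles = ["pair"] * k + ["a"] * (n_a - k) + ["b"] * (n_b - k)
    rng.shuffle(roles)

    a_ivs, b_ivs = [], []
    for slot_i, role in zip(idx, roles):
        chrom, s = all_slots[slot_i]
        base = s * slot_w
        # keep peaks inside the slot even after the overlap shift
        start = base + peak_len + int(rng.integers(0, peak_len))
        if role == "b":
            b_ivs.append(GenomicInterval(chrom, start, start + peak_len))
        elif role == "a":
            a_ivs.append(GenomicInterval(chrom, start, start + peak_len))
        else:
            shift = int(rng.integers(-(peak_len - 1), peak_len))
            b_ivs.append(GenomicInterval(chrom, start, start + peak_len))
            a_ivs.append(
                GenomicInterval(chrom, start + shift, start + shift + peak_len)
            )
    return PeakSet("A", a_ivs), PeakSet("B", b_ivs)


# ---------------------------------------------------------------------------
# coverage tracks


def make_coverage(
    truth: SynthTrackTruth,
    chrom_sizes: dict[str, int],
    bin_size: int = 50,
    seed: int | None = None,
) -> BinnedTrack:
    """Poisson per-bin counts with triangular enrichment over peaks.

    The rate of a background bin is ``background_rate``; within a peak the
    rate ramps linearly from background at the edges to
    ``background_rate * enrichment`` at the peak center.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    data = {}
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom] // bin_size
        lam = np.full(n, truth.background_rate, dtype=float)
        for iv in truth.peaks.by_chrom(chrom):
            center = (iv.start + iv.end) / 2
            half = max((iv.end - iv.start) / 2, 1.0)
            b0, b1 = iv.start // bin_size, min((iv.end - 1) // bin_size, n - 1)
            if b0 >= n:
                continue
            mids = (np.arange(b0, b1 + 1) + 0.5) * bin_size
            tri = np.clip(1.0 - np.abs(mids - center) / half, 0.0, 1.0)
            lam[b0 : b1 + 1] = truth.background_rate * (
                1.0 + (truth.enrichment - 1.0) * tri
            )
        data[chrom] = rng.poisson(lam).astype(float)
    return BinnedTrack(bin_size, data, dict(chrom_sizes))


# ---------------------------------------------------------------------------
# titrations


def make_titration(
    Kd: float,
    T0: float = 20.0,
    X_grid: tuple[float, ...] = (0, 1, 3, 10, 30, 100, 300, 1000),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """A titration series from the quadratic isotherm plus Gaussian noise.

    Defaults reproduce the experimental design: 20 nM labelled DNA titrated
    with protein at 0–1000 nM in the printed gradient. Noise is additive on
    the bound fraction and clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    X = np.asarray(X_grid, dtype=float)
    y = bound_fraction(T0, X, Kd)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=len(X)), 0.0, 1.0)
    return TitrationSeries(T0=T0, X=X, Y=y)
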