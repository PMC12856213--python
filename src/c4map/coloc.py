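"""Colocalization statistics for peak sets and binned coverage tracks.

Re-implements the comparison toolbox used to relate sequencing tracks and
peak calls from different probes: 1x-coverage (RPGC) normalization, Pearson
correlation over fixed genomic bins with blacklist and outlier handling,
asymmetric peak-overlap fractions, exclusive multiway ("upset")
intersection counts over merged union intervals, anchor-centered signal
profile matrices, and promoter/distal partitioning around TSSs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .formats import BinnedTrack, GenomicInterval, PeakSet, TssTable

__all__ = [
    "CorrelationMatrix",
    "UpsetCounts",
    "ProfileMatrix",
    "rpgc_normalize",
    "overlap_fraction",
    "upset_counts",
    "track_correlation",
    "profile_matrix",
    "promoter_partition",
    "mean_signal_at",
]


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: np.ndarray
    n_bins_used: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.labels)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class UpsetCounts:
    """Exclusive intersection sizes: each merged union interval is counted
    under exactly the subset of input sets it touches (>= 1 bp)."""

    labels: list[str]
    counts: dict[tuple[str, ...], int]

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ProfileMatrix:
    """Region-anchored signal matrix: one row per region center, columns
    covering center +/- flank at ``bin`` resolution. ``row_order`` sorts rows
    by descending mean (ties keep input order)."""

    centers: list[tuple[str, int]]
    flank: int
    bin: int
    matrix: np.ndarray
    row_order: np.ndarray

    def sorted_matrix(self) -> np.ndarray:
        return self.matrix[self.row_order]

    def row_means(self) -> np.ndarray:
        return self.matrix.mean(axis=1)


# ---------------------------------------------------------------------------
# track operations


def rpgc_normalize(track: BinnedTrack) -> BinnedTrack:
    """Scale all bins by one global constant so the genome-wide mean is 1.

    This is reads-per-genomic-content (1x coverage) normalization applied
    at the bin level.
    """
    if track.n_bins() == 0:
        raise ValueError("track has no bins")
    mean = float(track.concat().mean())
    if mean == 0:
        raise ValueError("cannot RPGC-normalize an all-zero track")
    return track.scaled(1.0 / mean)


def _rebin(track: BinnedTrack, bin_size: int) -> BinnedTrack:
    if bin_size == track.bin_size:
        return track
    if bin_size % track.bin_size:
        raise ValueError(
            f"target bin {bin_size} must be a multiple of track bin {track.bin_size}"
        )
    k = bin_size // track.bin_size
    data = {}
    for chrom, vec in track.data.items():
        n = (len(vec) // k) * k
        data[chrom] = vec[:n].reshape(-1, k).mean(axis=1)
    sizes = {c: (len(v) * bin_size) for c, v in data.items()}
    return BinnedTrack(bin_size, data, sizes)


def _blacklist_mask(
    chrom: str, n_bins: int, bin_size: int, blacklist: PeakSet | None
) -> np.ndarray:
    """True for bins that survive (do not intersect the blacklist)."""
    keep = np.ones(n_bins, dtype=bool)
    if blacklist is None:
        return keep
    starts, ends = blacklist.merged_arrays(chrom)
    for s, e in zip(starts, ends):
        b0 = s // bin_size
        b1 = min((e - 1) // bin_size, n_bins - 1)
        if b0 < n_bins:
            keep[b0 : b1 + 1] = False
    return keep


def track_correlation(
    tracks: list[BinnedTrack],
    labels: list[str] | None = None,
    bin_size: int = 300,
    blacklist: PeakSet | None = None,
    remove_outliers: bool = False,
    mad_factor: float = 200.0,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise correlation of coverage tracks over fixed genomic bins.

    Tracks are re-binned to ``bin_size`` by averaging, blacklist-intersecting
    bins are dropped globally, and (optionally) for each pair any bin where
    either track exceeds its own median + ``mad_factor`` * MAD is dropped
    before computing the coefficient. Pearson by default; ``method="spearman"``
    ranks the surviving bins first.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    labels = labels or [f"track{i}" for i in range(len(tracks))]
    rebinned = [_rebin(t, bin_size) for t in tracks]
    chroms = sorted(set.intersection(*(set(t.data) for t in rebinned)))
    if not chroms:
        raise ValueError("tracks share no chromosomes")

    # align chromosome-wise: each chromosome contributes the bins all
    # tracks have for it, in sorted-chromosome order
    parts: list[list[np.ndarray]] = [[] for _ in rebinned]
    keep_parts: list[np.ndarray] = []
    for c in chroms:
        n = min(len(t.data[c]) for t in rebinned)
        if n == 0:
            continue
        for i, t in enumerate(rebinned):
            parts[i].append(t.data[c][:n])
        keep_parts.append(_blacklist_mask(c, n, bin_size, blacklist))
    keep = np.concatenate(keep_parts)
    mat = np.stack([np.concatenate(p) for p in parts])[:, keep]
    if mat.shape[1] < 2:
        raise ValueError("fewer than 2 bins survive filtering")

    thresholds = np.full(len(tracks), np.inf)
    if remove_outliers:
        for i, v in enumerate(mat):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad > 0:
                thresholds[i] = med + mad_factor * mad

    k = len(tracks)
    r = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        ok = (mat[i] <= thresholds[i]) & (mat[j] <= thresholds[j])
        if ok.sum() < 2:
            raise ValueError(f"fewer than 2 bins survive for pair ({i},{j})")
        xi, xj = mat[i][ok], mat[j][ok]
        if method == "spearman":
            from scipy.stats import rankdata

            xi, xj = rankdata(xi), rankdata(xj)
        elif method != "pearson":
            raise ValueError("method must be pearson or spearman")
        with np.errstate(invalid="ignore"):
            rij = np.corrcoef(xi, xj)[0, 1]
        r[i, j] = r[j, i] = rij
    return CorrelationMatrix(labels=list(labels), r=r, n_bins_used=int(keep.sum()))


# ---------------------------------------------------------------------------
# peak set operations


def overlap_fraction(a: PeakSet, b: PeakSet, min_bp: int = 1) -> float:
    """Fraction of A peaks overlapping at least one B peak by >= ``min_bp``.

    Asymmetric by design: A is the numerator set.
    """
    if len(a) == 0:
        raise ValueError("A must be non-empty")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    hit = 0
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.chroms():
        ivs_b = b.by_chrom(chrom)
        starts = np.array([iv.start for iv in ivs_b], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs_b], dtype=np.int64)
        b_by_chrom[chrom] = (starts, ends)
    for iv in a:
        starts, ends = b_by_chrom[iv.chrom]
        if len(starts) == 0:
            continue
        ov = np.minimum(iv.end, ends) - np.maximum(iv.start, starts)
        if ov.max(initial=0) >= min_bp:
            hit += 1
    return hit / len(a)


def upset_counts(sets: list[PeakSet]) -> UpsetCounts:
    """Exclusive multiway intersection counts over merged union intervals.

    The union of all intervals is merged; each merged interval is assigned
    to the exact subset of input sets it intersects by >= 1 bp. The counts
    sum to the number of merged union intervals.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    labels = [s.label for s in sets]
    union = PeakSet("union", [iv for s in sets for iv in s])
    counts: dict[tuple[str, ...], int] = {}
    for chrom in union.chroms():
        u_starts, u_ends = union.merged_arrays(chrom)
        merged = [(s.merged_arrays(chrom)) for s in sets]
        for s0, e0 in zip(u_starts, u_ends):
            members = []
            for lbl, (ms, me) in zip(labels, merged):
                if len(ms) == 0:
                    continue
                j = np.searchsorted(ms, e0, side="left") - 1
                # any set interval starting before the union end that ends
                # after the union start intersects it
                if j >= 0 and me[j] > s0:
                    members.append(lbl)
                elif j + 1 < len(ms) and ms[j + 1] < e0 and me[j + 1] > s0:
                    members.append(lbl)
            key = tuple(members)
            counts[key] = counts.get(key, 0) + 1
    return UpsetCounts(labels=labels, counts=counts)


def promoter_partition(
    hits: PeakSet, tss: TssTable, window: int = 3000
) -> tuple[PeakSet, PeakSet]:
    """Split hits into promoter (overlapping TSS +/- window) and distal.

    The promoter region of a TSS at position p is [p - window, p + window + 1)
    (half-open, containing the window on both sides plus the TSS base); a
    hit is promoter-assigned on >= 1 bp overlap with any such region. The
    partition is exhaustive and disjoint.
    """
    if len(tss) == 0:
        raise ValueError("TSS table is empty")
    regions: dict[str, list[GenomicInterval]] = {}
    for chrom, pos, strand, name in tss:
        start = max(0, pos - window)
        regions.setdefault(chrom, []).append(
            GenomicInterval(chrom, start, pos + window + 1)
        )
    windows = PeakSet("promoters", [iv for ivs in regions.values() for iv in ivs])
    merged = {c: windows.merged_arrays(c) for c in windows.chroms()}

    promoter, distal = [], []
    for iv in hits:
        ms, me = merged.get(iv.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        is_promoter = False
        if len(ms):
            j = np.searchsorted(ms, iv.end, side="left") - 1
            is_promoter = j >= 0 and me[j] > iv.start
        (promoter if is_promoter else distal).append(iv)
    return (
        PeakSet(f"{hits.label}_promoter", promoter),
        PeakSet(f"{hits.label}_distal", distal),
    )


# ---------------------------------------------------------------------------
# profiles


def _sample_positions(track: BinnedTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Track value at each base position; 0 outside the binned extent."""
    vec = track.data.get(chrom)
    out = np.zeros(positions.shape, dtype=float)
    if vec is None or len(vec) == 0:
        return out
    idx = positions // track.bin_size
    ok = (positions >= 0) & (idx < len(vec))
    out[ok] = vec[idx[ok]]
    return out


def profile_matrix(
    track: BinnedTrack, regions: PeakSet, flank: int = 1000, bin: int = 50
) -> ProfileMatrix:
    """Signal matrix over region centers +/- flank at ``bin`` resolution.

    The center of a region [start, end) is floor((start + end) / 2); column
    j averages per-base track values over [center - flank + j*bin, ... + bin).
    Bases outside the chromosome's binned extent contribute 0. ``row_order``
    sorts rows by descending mean, stable in input order.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    if flank % bin:
        raise ValueError("flank must be a multiple of bin")
    ncols = 2 * flank // bin
    centers = [(iv.chrom, (iv.start + iv.end) // 2) for iv in regions]
    rows = np.empty((len(centers), ncols), dtype=float)
    offsets = np.arange(-flank, flank)
    for i, (chrom, c) in enumerate(centers):
        per_base = _sample_positions(track, chrom, c + offsets)
        rows[i] = per_base.reshape(ncols, bin).mean(axis=1)
    order = np.argsort(-rows.mean(axis=1), kind="stable")
    return ProfileMatrix(centers=centers, flank=flank, bin=bin, matrix=rows, row_order=order)


def mean_signal_at(track: BinnedTrack, anchors: TssTable, flank: int = 3000) -> np.ndarray:
    """Composite (column-mean) signal profile around TSS anchors.

    Rows for minus-strand anchors are reversed before averaging so the
    profile reads 5' -> 3' relative to each gene. Resolution is the track's
    own bin size.
    """
    if len(anchors) == 0:
        raise ValueError("anchor table is empty")
    bin = track.bin_size
    if flank % bin:
        raise ValueError("flank must be a multiple of the track bin size")
    ncols = 2 * flank // bin
    offsets = np.arange(-flank, flank)
    acc = np.zeros(ncols, dtype=float)
    for chrom, pos, strand, _name in anchors:
        per_base = _sample_positions(track, chrom, pos + offsets)
        row = per_base.reshape(ncols, bin).mean(axis=1)
        if strand == "-":
            row = row[::-1]
        acc += row
    return acc / len(anchors)
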