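"""Motif grammars for C-rich ssDNA (C4) and putative G-quadruplex sequences.

The grammars model what a C-rich ssDNA probe can recognize and what the
complementary G-rich strand can fold into:

* **unit** — the minimal probe-recognizable element: two maximal C-tracts of
  >= 3 C separated by a flexible spacer of 1–7 nt (CCCN1–7CCC), or a single
  uninterrupted run of >= 7 C.
* **C4** — the C-rich complement of a G-quadruplex: consecutive maximal
  C-tracts (>= 3 C each) joined by loops of 1–7 nt. Binding requires at
  least two tracts; the canonical complement has four.
* **PQS classes** on the G-rich strand: canonical (four G>=3 tracts, loops
  1–7), two-quartet (four G>=2 tracts), G-vacancy-bearing (exactly one GG
  among four tracts), long-loop (loops up to 15 nt with at least one >= 8,
  disjoint from canonical), and bulged (exactly one tract interrupted by a
  1–3 nt non-G bulge).

Tracts are *maximal* runs: a hit's first/last tract cannot be extended, and
loop bases may be anything except N (a hit never spans an assembly gap).
Scanning covers both strands; minus-strand hits are reported in plus-strand
coordinates with ``strand="-"``. Overlapping candidates are resolved
leftmost-greedy, preferring more tracts, then longer span, independently on
each strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .formats import GenomicInterval, PeakSet

__all__ = [
    "MotifGrammar",
    "CTract",
    "MotifHit",
    "PQS_CLASSES",
    "revcomp",
    "find_tracts",
    "scan_units",
    "scan_c4",
    "scan_pqs",
    "hits_to_peakset",
]

PQS_CLASSES = ("canonical4G", "twoQuartet", "GVBQ", "longLoop15", "bulged")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifGrammar:
    """Parameters of a tract/loop motif grammar."""

    tract_base: str
    min_tract_len: int
    n_tracts: int
    loop_min: int
    loop_max: int
    variant_class: str
    single_run_min: int | None = None

    def __post_init__(self) -> None:
        if self.tract_base not in ("C", "G"):
            raise ValueError("tract_base must be C or G")
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min > loop_max")
        if self.n_tracts < 2 and self.single_run_min is None:
            raise ValueError("n_tracts must be >= 2 unless a single-run rule applies")


#: Grammar of the minimal probe-recognizable C-rich element.
UNIT_GRAMMAR = MotifGrammar("C", 3, 2, 1, 7, "unit", single_run_min=7)
#: Grammar of the C-rich G4 complement (canonical form has four tracts).
C4_GRAMMAR = MotifGrammar("C", 3, 4, 1, 7, "C4")


@dataclass(frozen=True)
class CTract:
    """A maximal run of the tract base within a sequence (offsets, half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in plus-strand coordinates of the scanned sequence.

    ``strand`` is the strand carrying the tract-base-rich pattern; ``tracts``
    and ``spacer_lengths`` describe the pattern on that strand, but ``start``
    and ``end`` always index the scanned (+) sequence.
    """

    start: int
    end: int
    strand: str
    variant_class: str
    tracts: tuple[CTract, ...]
    spacer_lengths: tuple[int, ...] = field(default=())

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty hit span")
        for a, b in zip(self.tracts, self.tracts[1:]):
            if b.start < a.end:
                raise ValueError("tracts overlap or out of order")


_RUN_RE = {base: re.compile(f"{base}+") for base in "ACGT"}


def find_tracts(seq: str, base: str, min_len: int) -> list[CTract]:
    """All maximal runs of ``base`` with length >= ``min_len``, left to right."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if base not in ("C", "G"):
        raise ValueError("tract base must be C or G")
    return [
        CTract(m.start(), m.end())
        for m in _RUN_RE[base].finditer(seq)
        if m.end() - m.start() >= min_len
    ]


def _gap_ok(seq: str, a: CTract, b: CTract, lo: int, hi: int) -> bool:
    gap = b.start - a.end
    return lo <= gap <= hi and "N" not in seq[a.end : b.start]


def _spacers(tracts: tuple[CTract, ...]) -> tuple[int, ...]:
    return tuple(b.start - a.end for a, b in zip(tracts, tracts[1:]))


# ---------------------------------------------------------------------------
# single-strand scanners (plus strand of the given sequence)


def _scan_units_one_strand(seq: str) -> list[MotifHit]:
    tracts = find_tracts(seq, "C", 3)
    hits: list[MotifHit] = []
    i = 0
    while i < len(tracts):
        t = tracts[i]
        # a two-tract unit is preferred over the single-run rule
        if i + 1 < len(tracts) and _gap_ok(seq, t, tracts[i + 1], 1, 7):
            pair = (t, tracts[i + 1])
            hits.append(
                MotifHit(t.start, tracts[i + 1].end, "+", "unit", pair, _spacers(pair))
            )
            i += 2
        elif t.length >= 7:
            hits.append(MotifHit(t.start, t.end, "+", "unit", (t,)))
            i += 1
        else:
            i += 1
    return hits


def _chain_scan(
    seq: str, base: str, min_tract_len: int, loop_min: int, loop_max: int,
    min_tracts: int, variant_class: str,
) -> list[MotifHit]:
    """Partition tracts into maximal chains linked by admissible loops.

    Chains are unique (the linkage relation between successive maximal runs
    is deterministic), which realizes leftmost-greedy resolution with
    maximal tract count.
    """
    tracts = find_tracts(seq, base, min_tract_len)
    hits: list[MotifHit] = []
    chain: list[CTract] = []

    def flush() -> None:
        if len(chain) >= min_tracts:
            tup = tuple(chain)
            hits.append(
                MotifHit(tup[0].start, tup[-1].end, "+", variant_class, tup, _spacers(tup))
            )

    for t in tracts:
        if chain and _gap_ok(seq, chain[-1], t, loop_min, loop_max):
            chain.append(t)
        else:
            flush()
            chain = [t]
    flush()
    return hits


def _window_scan(
    seq: str,
    candidates: list[tuple[CTract, ...]],
    loop_min: int,
    loop_max: int,
    n: int,
    variant_class: str,
    window_ok,
) -> list[MotifHit]:
    """Generic fixed-n-tract window scan with greedy overlap resolution.

    ``candidates`` are tract objects (each a tuple of 1+ maximal runs — a
    plain tract or a bulged composite), sorted by start. Windows are chains
    of ``n`` candidates whose successive gaps lie in [loop_min, loop_max]
    (N-free); ``window_ok`` filters composition. Overlaps resolve
    leftmost-greedy, then maximal span.
    """
    from bisect import bisect_left, bisect_right

    spans: list[tuple[int, int, tuple[tuple[CTract, ...], ...]]] = []
    candidates.sort(key=lambda c: (c[0].start, -(c[-1].end)))
    m = len(candidates)
    starts = [c[0].start for c in candidates]

    def cand_start(c: tuple[CTract, ...]) -> int:
        return c[0].start

    def cand_end(c: tuple[CTract, ...]) -> int:
        return c[-1].end

    def extend(path: list[tuple[CTract, ...]]) -> None:
        if len(path) == n:
            if window_ok(path):
                spans.append((cand_start(path[0]), cand_end(path[-1]), tuple(path)))
            return
        last_end = cand_end(path[-1])
        lo = bisect_left(starts, last_end + loop_min)
        hi = bisect_right(starts, last_end + loop_max)
        for j in range(lo, hi):
            c = candidates[j]
            if "N" in seq[last_end : cand_start(c)]:
                continue
            extend(path + [c])

    for j in range(m):
        extend([candidates[j]])

    spans.sort(key=lambda t: (t[0], -t[1]))
    hits: list[MotifHit] = []
    cursor = -1
    for s, e, path in spans:
        if s <= cursor:
            continue
        flat = tuple(run for cand in path for run in cand)
        hits.append(MotifHit(s, e, "+", variant_class, flat))
        cursor = e - 1
    return hits


def _scan_pqs_one_strand(seq: str, variant_class: str) -> list[MotifHit]:
    if variant_class == "canonical4G":
        return _chain_scan(seq, "G", 3, 1, 7, 4, variant_class)
    if variant_class == "twoQuartet":
        return _chain_scan(seq, "G", 2, 1, 7, 4, variant_class)

    if variant_class == "GVBQ":
        runs = find_tracts(seq, "G", 2)
        cands = [(r,) for r in runs]

        def ok(path) -> bool:
            lens = [c[0].length for c in path]
            return sum(1 for L in lens if L == 2) == 1 and all(
                L >= 3 for L in lens if L != 2
            )

        return _window_scan(seq, cands, 1, 7, 4, variant_class, ok)

    if variant_class == "longLoop15":
        runs = find_tracts(seq, "G", 3)
        cands = [(r,) for r in runs]

        def ok(path) -> bool:
            gaps = [
                b[0].start - a[-1].end for a, b in zip(path, path[1:])
            ]
            return any(g >= 8 for g in gaps)  # disjoint from canonical4G

        return _window_scan(seq, cands, 1, 15, 4, variant_class, ok)

    if variant_class == "bulged":
        runs = find_tracts(seq, "G", 1)
        plain: list[tuple[CTract, ...]] = [(r,) for r in runs if r.length >= 3]
        split: list[tuple[CTract, ...]] = []
        for a, b in zip(runs, runs[1:]):
            gap = b.start - a.end
            if 1 <= gap <= 3 and a.length + b.length >= 3 and "N" not in seq[a.end : b.start]:
                split.append((a, b))

        def ok(path) -> bool:
            return sum(1 for c in path if len(c) == 2) == 1

        return _window_scan(seq, plain + split, 1, 7, 4, variant_class, ok)

    raise ValueError(f"unknown PQS class {variant_class!r}")


# ---------------------------------------------------------------------------
# double-strand wrappers


def _mirror(hits: list[MotifHit], seq_len: int) -> list[MotifHit]:
    """Map hits found on the reverse complement back to + coordinates."""
    out = []
    for h in hits:
        tracts = tuple(
            CTract(seq_len - t.end, seq_len - t.start) for t in reversed(h.tracts)
        )
        out.append(
            MotifHit(
                seq_len - h.end,
                seq_len - h.start,
                "-",
                h.variant_class,
                tracts,
                h.spacer_lengths[::-1],
            )
        )
    return out


def _both_strands(seq: str, scan_one, strands: str) -> list[MotifHit]:
    hits: list[MotifHit] = []
    if strands in ("+", "both"):
        hits.extend(scan_one(seq))
    if strands in ("-", "both"):
        hits.extend(_mirror(scan_one(revcomp(seq)), len(seq)))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def scan_units(seq: str, strands: str = "both") -> list[MotifHit]:
    """Scan for minimal probe-recognizable C-rich units.

    A unit is two maximal C-tracts (>= 3 C) with a 1–7 nt spacer, or one
    maximal run of >= 7 C. A lone run of 6 C is *not* a unit. Resolution is
    leftmost-greedy per strand, preferring the two-tract form.
    """
    return _both_strands(seq, _scan_units_one_strand, strands)


def scan_c4(seq: str, min_tracts: int = 4, strands: str = "both") -> list[MotifHit]:
    """Scan for C4 motifs: chains of maximal C-tracts (>= 3 C) linked by
    1–7 nt loops, with at least ``min_tracts`` tracts (2, 3 or 4).

    Each hit is a maximal chain, so the four-tract hit set is contained
    (span-wise) in the two-tract hit set.
    """
    if min_tracts not in (2, 3, 4):
        raise ValueError("min_tracts must be 2, 3 or 4")
    return _both_strands(
        seq, lambda s: _chain_scan(s, "C", 3, 1, 7, min_tracts, "C4"), strands
    )


def scan_pqs(seq: str, variant_class: str, strands: str = "both") -> list[MotifHit]:
    """Scan for a putative G4-forming sequence class on both strands.

    Classes: canonical4G, twoQuartet, GVBQ, longLoop15, bulged (see module
    docstring). Minus-strand hits carry + coordinates and ``strand="-"``.
    """
    if variant_class not in PQS_CLASSES:
        raise ValueError(
            f"unknown class {variant_class!r}; choose from {PQS_CLASSES}"
        )
    return _both_strands(
        seq, lambda s: _scan_pqs_one_strand(s, variant_class), strands
    )


def hits_to_peakset(
    hits: list[MotifHit], chrom: str, offset: int = 0, label: str = "hits"
) -> PeakSet:
    """Convert hits from one sequence into a BED-ready PeakSet.

    The name field carries the variant class, the score the tract count.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return PeakSet(
        label,
        [
            GenomicInterval(
                chrom,
                offset + h.start,
                offset + h.end,
                h.strand,
                h.variant_class,
                float(h.n_tracts),
            )
            for h in hits
        ],
    )
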