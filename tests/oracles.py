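"""Independent brute-force oracles for cross-checking the package.

Everything here is deliberately written from first principles (explicit
loops, per-base boolean masks, root finding on the mass-action equations)
and shares no code path with the implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

# ---------------------------------------------------------------------------
# scanning oracles


def maximal_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` found by a character walk."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _greedy(spans: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    """Resolve candidates (start, end, n_tracts) leftmost-greedy with
    maximal tract count, then maximal span; no re-scan inside a consumed hit."""
    spans = sorted(spans, key=lambda t: (t[0], -t[2], -t[1]))
    out: list[tuple[int, int]] = []
    consumed_until = -1
    for s, e, _k in spans:
        if s > consumed_until:
            out.append((s, e))
            consumed_until = e - 1
    return out


def chain_spans_oracle(
    seq: str, base: str, min_tract: int, loop_min: int, loop_max: int, min_tracts: int
) -> list[tuple[int, int]]:
    """All chain-grammar hit spans on the given strand, by enumerating every
    consecutive-tract window and resolving greedily."""
    runs = maximal_runs(seq, base, min_tract)
    cands = []
    for i in range(len(runs)):
        for j in range(i + min_tracts - 1, len(runs)):
            ok = True
            for k in range(i, j):
                gap = runs[k + 1][0] - runs[k][1]
                if not (loop_min <= gap <= loop_max) or "N" in seq[runs[k][1] : runs[k + 1][0]]:
                    ok = False
                    break
            if ok:
                cands.append((runs[i][0], runs[j][1], j - i + 1))
            else:
                break
    return _greedy(cands)


def unit_spans_oracle(seq: str) -> list[tuple[int, int]]:
    """Probe-unit spans: adjacent tract pairs with 1-7 nt spacers, or lone
    runs >= 7; pairs preferred, greedy left to right."""
    runs = maximal_runs(seq, "C", 3)
    cands = []
    for i in range(len(runs) - 1):
        gap = runs[i + 1][0] - runs[i][1]
        if 1 <= gap <= 7 and "N" not in seq[runs[i][1] : runs[i + 1][0]]:
            cands.append((runs[i][0], runs[i + 1][1], 2))
    for s, e in runs:
        if e - s >= 7:
            cands.append((s, e, 1))
    return _greedy(cands)


def window_spans_oracle(
    seq: str, variant_class: str
) -> list[tuple[int, int]]:
    """Fixed-four-tract PQS classes by pruned exhaustive enumeration."""
    if variant_class == "GVBQ":
        objs = [((s, e),) for s, e in maximal_runs(seq, "G", 2)]
        loop_max = 7

        def comp_ok(lens_flags):
            lens = [o[-1][1] - o[0][0] for o in lens_flags]  # plain objects only
            return sum(1 for L in lens if L == 2) == 1 and all(
                L >= 3 for L in lens if L != 2
            )

        def gaps_ok(gaps):
            return all(1 <= g <= 7 for g in gaps)

    elif variant_class == "longLoop15":
        objs = [((s, e),) for s, e in maximal_runs(seq, "G", 3)]
        loop_max = 15

        def comp_ok(path):
            return True

        def gaps_ok(gaps):
            return all(1 <= g <= 15 for g in gaps) and any(g >= 8 for g in gaps)

    elif variant_class == "bulged":
        runs1 = maximal_runs(seq, "G", 1)
        objs = [((s, e),) for s, e in runs1 if e - s >= 3]
        for (s1, e1), (s2, e2) in zip(runs1, runs1[1:]):
            gap = s2 - e1
            if 1 <= gap <= 3 and (e1 - s1) + (e2 - s2) >= 3 and "N" not in seq[e1:s2]:
                objs.append(((s1, e1), (s2, e2)))
        loop_max = 7

        def comp_ok(path):
            return sum(1 for o in path if len(o) == 2) == 1

        def gaps_ok(gaps):
            return all(1 <= g <= 7 for g in gaps)

    else:
        raise ValueError(variant_class)

    objs.sort(key=lambda o: (o[0][0], -o[-1][1]))
    m = len(objs)
    cands = []
    for a in range(m):
        ea = objs[a][-1][1]
        for b in range(a + 1, m):
            if objs[b][0][0] > ea + loop_max:
                break
            if objs[b][0][0] <= ea:
                continue
            eb = objs[b][-1][1]
            for c in range(a + 1, m):
                if objs[c][0][0] > eb + loop_max:
                    break
                if objs[c][0][0] <= eb:
                    continue
                ec = objs[c][-1][1]
                for d in range(a + 1, m):
                    if objs[d][0][0] > ec + loop_max:
                        break
                    if objs[d][0][0] <= ec:
                        continue
                    path = (objs[a], objs[b], objs[c], objs[d])
                    gaps = [
                        path[k + 1][0][0] - path[k][-1][1] for k in range(3)
                    ]
                    if not gaps_ok(gaps):
                        continue
                    if any(
                        "N" in seq[path[k][-1][1] : path[k + 1][0][0]]
                        for k in range(3)
                    ):
                        continue
                    if not comp_ok(path):
                        continue
                    cands.append((path[0][0][0], path[-1][-1][1], 4))
    return _greedy(cands)


def revcomp_oracle(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def both_strand_spans(one_strand_fn, seq: str) -> list[tuple[int, int, str]]:
    """Run a single-strand span oracle on both strands, minus-strand spans
    mapped back to plus coordinates."""
    n = len(seq)
    plus = [(s, e, "+") for s, e in one_strand_fn(seq)]
    minus = [(n - e, n - s, "-") for s, e in one_strand_fn(revcomp_oracle(seq))]
    return sorted(plus + minus)


# ---------------------------------------------------------------------------
# binding oracle


def equilibrium_bound_fraction(T0: float, X: float, Kd: float) -> float:
    """Bound fraction by numerically solving the mass-action equilibrium
    Kd = [P_free][D_free]/[PD] for the complex concentration."""
    if X == 0:
        return 0.0
    if Kd == 0:
        return min(T0, X) / T0

    def f(c):
        return (T0 - c) * (X - c) - Kd * c

    hi = min(T0, X)
    c = brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15)
    return c / T0


# ---------------------------------------------------------------------------
# interval oracles (per-base boolean masks)


def overlap_fraction_oracle(a_ivs, b_ivs, min_bp: int = 1) -> float:
    """All-pairs overlap check; a_ivs/b_ivs are (chrom, start, end) tuples."""
    hit = 0
    for ca, sa, ea in a_ivs:
        best = 0
        for cb, sb, eb in b_ivs:
            if ca == cb:
                best = max(best, min(ea, eb) - max(sa, sb))
        hit += best >= min_bp
    return hit / len(a_ivs)


def upset_counts_oracle(labelled_sets, span: int):
    """Exclusive intersection counts via per-base masks over [0, span).

    ``labelled_sets``: list of (label, [(chrom, start, end), ...]).
    Returns dict mapping label-tuples to counts.
    """
    chroms = sorted({c for _lbl, ivs in labelled_sets for c, _s, _e in ivs})
    counts: dict[tuple[str, ...], int] = {}
    for chrom in chroms:
        masks = {}
        union = np.zeros(span, dtype=bool)
        for lbl, ivs in labelled_sets:
            m = np.zeros(span, dtype=bool)
            for c, s, e in ivs:
                if c == chrom:
                    m[s:e] = True
            masks[lbl] = m
            union |= m
        # connected components of the union mask
        edges = np.flatnonzero(np.diff(np.concatenate([[0], union.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            key = tuple(
                lbl for lbl, _ivs in labelled_sets if masks[lbl][s:e].any()
            )
            counts[key] = counts.get(key, 0) + 1
    return counts
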