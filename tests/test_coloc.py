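"""Colocalization statistics: examples, invariants, brute-force equivalence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from c4map.coloc import (
    mean_signal_at,
    overlap_fraction,
    profile_matrix,
    promoter_partition,
    rpgc_normalize,
    track_correlation,
    upset_counts,
)
from c4map.formats import BinnedTrack, GenomicInterval, PeakSet, TssTable

from .oracles import overlap_fraction_oracle, upset_counts_oracle


def peaks(label, ivs):
    return PeakSet(label, [GenomicInterval("chr1", s, e) for s, e in ivs])


def track(values, bin_size=10, chrom="chr1"):
    v = np.asarray(values, dtype=float)
    return BinnedTrack(bin_size, {chrom: v}, {chrom: len(v) * bin_size})


random_intervals = st.lists(
    st.tuples(st.integers(0, 4900), st.integers(1, 120)).map(
        lambda t: (t[0], t[0] + t[1])
    ),
    min_size=1,
    max_size=60,
)


class TestRpgc:
    def test_constant_track(self):
        t = rpgc_normalize(track([2, 2, 2]))
        assert np.allclose(t.data["chr1"], 1.0)

    def test_mean_one(self):
        t = rpgc_normalize(track([0, 4]))
        assert np.allclose(t.data["chr1"], [0, 2])

    def test_idempotent(self):
        t = rpgc_normalize(track([1, 3, 5, 7]))
        t2 = rpgc_normalize(t)
        assert np.allclose(t.data["chr1"], t2.data["chr1"], atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rpgc_normalize(track([0, 0]))


class TestOverlapFraction:
    def test_identical_sets(self):
        a = peaks("a", [(0, 10), (20, 30), (40, 50)])
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint_sets(self):
        a = peaks("a", [(0, 10)])
        b = peaks("b", [(20, 30)])
        assert overlap_fraction(a, b) == 0.0

    def test_planted_fraction(self):
        a_ivs = [(i * 100, i * 100 + 50) for i in range(100)]
        b_ivs = [(i * 100 + 25, i * 100 + 60) for i in range(40)]  # touch first 40
        assert overlap_fraction(peaks("a", a_ivs), peaks("b", b_ivs)) == 0.40

    def test_min_bp_threshold(self):
        a = peaks("a", [(0, 10)])
        b = peaks("b", [(8, 20)])
        assert overlap_fraction(a, b, min_bp=2) == 1.0
        assert overlap_fraction(a, b, min_bp=3) == 0.0

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(PeakSet("a", []), peaks("b", [(0, 1)]))

    @given(random_intervals, random_intervals)
    def test_matches_brute_force(self, a_ivs, b_ivs):
        got = overlap_fraction(peaks("a", a_ivs), peaks("b", b_ivs))
        want = overlap_fraction_oracle(
            [("chr1", s, e) for s, e in a_ivs], [("chr1", s, e) for s, e in b_ivs]
        )
        assert got == pytest.approx(want)

    @given(random_intervals, random_intervals, random_intervals)
    def test_monotone_in_b(self, a_ivs, b_ivs, extra):
        a = peaks("a", a_ivs)
        assert overlap_fraction(a, peaks("b", b_ivs + extra)) >= overlap_fraction(
            a, peaks("b", b_ivs)
        )


class TestUpsetCounts:
    def test_overlapping_pair_merges(self):
        res = upset_counts([peaks("A", [(0, 10)]), peaks("B", [(5, 15)])])
        assert res.counts == {("A", "B"): 1}

    def test_disjoint_pair(self):
        res = upset_counts([peaks("A", [(0, 10)]), peaks("B", [(20, 30)])])
        assert res.counts == {("A",): 1, ("B",): 1}

    def test_three_identical_singletons(self):
        sets = [peaks(lbl, [(5, 9)]) for lbl in "ABC"]
        assert upset_counts(sets).counts == {("A", "B", "C"): 1}

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            upset_counts([peaks("A", [(0, 1)])])

    @given(random_intervals, random_intervals, random_intervals)
    def test_matches_brute_force_and_conserves_mass(self, a, b, c):
        sets = [peaks("A", a), peaks("B", b), peaks("C", c)]
        res = upset_counts(sets)
        want = upset_counts_oracle(
            [(lbl, [("chr1", s, e) for s, e in ivs]) for lbl, ivs in zip("ABC", [a, b, c])],
            span=5200,
        )
        assert res.counts == want
        union = PeakSet("u", [iv for s in sets for iv in s])
        n_union = len(union.merged_arrays("chr1")[0])
        assert res.total() == n_union


class TestTrackCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        t = track(rng.poisson(5, 2000), bin_size=50)
        cm = track_correlation([t, t], bin_size=300)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        t = track(rng.poisson(5, 2000).astype(float), bin_size=50)
        cm = track_correlation([t, t.scaled(5.0)], bin_size=300)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = track(rng.poisson(10, 10_000), bin_size=300)
        b = track(rng.poisson(10, 10_000), bin_size=300)
        cm = track_correlation([a, b], bin_size=300)
        assert abs(cm.r[0, 1]) < 0.05

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        ts = [track(rng.poisson(8, 1200), bin_size=100) for _ in range(3)]
        cm = track_correlation(ts, bin_size=300)
        assert np.allclose(cm.r, cm.r.T)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.all(np.abs(cm.r) <= 1 + 1e-12)

    def test_blacklist_bins_dropped(self):
        a = track(np.arange(10, dtype=float), bin_size=100)
        b = track(np.arange(10, dtype=float)[::-1].copy(), bin_size=100)
        bl = peaks("bl", [(0, 500)])
        cm = track_correlation([a, b], bin_size=100, blacklist=bl)
        assert cm.n_bins_used == 5

    def test_outlier_removal_restores_correlation(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(10, 5000).astype(float)
        a = track(np.clip(base + rng.normal(0, 1, 5000), 0, None), bin_size=100)
        spiked = np.clip(base + rng.normal(0, 1, 5000), 0, None)
        spiked[100] = 1e6  # one artifact bin
        b = track(spiked, bin_size=100)
        plain = track_correlation([a, b], bin_size=100).r[0, 1]
        robust = track_correlation(
            [a, b], bin_size=100, remove_outliers=True
        ).r[0, 1]
        assert robust > 0.9 > plain


class TestProfileMatrix:
    def test_constant_track(self):
        t = track(np.ones(100), bin_size=10)
        regions = peaks("r", [(200, 300), (500, 600)])
        pm = profile_matrix(t, regions, flank=100, bin=10)
        assert np.allclose(pm.matrix, 1.0)
        assert list(pm.row_order) == [0, 1]

    def test_triangular_peak_max_at_center(self):
        n = 200
        v = np.zeros(n)
        v[40:61] = np.concatenate([np.arange(10), [10], np.arange(10)[::-1]])
        t = track(v, bin_size=10)
        pm = profile_matrix(t, peaks("r", [(495, 505)]), flank=100, bin=10)
        row = pm.matrix[0]
        assert row.argmax() in (len(row) // 2 - 1, len(row) // 2)

    def test_row_order_by_descending_mean(self):
        v = np.zeros(300)
        v[10:20] = 2.0   # region at bin 10-20 -> mean 2
        v[100:110] = 5.0
        t = track(v, bin_size=10)
        regions = peaks("r", [(100, 200), (1000, 1100)])
        pm = profile_matrix(t, regions, flank=50, bin=10)
        assert list(pm.row_order) == [1, 0]
        means = pm.row_means()[pm.row_order]
        assert np.all(np.diff(means) <= 0)

    def test_out_of_chromosome_zero(self):
        t = track(np.ones(10), bin_size=10)
        # center = 1: columns left of the chromosome are zero; the column
        # straddling position 0 averages one covered base with nine zeros
        pm = profile_matrix(t, peaks("r", [(0, 2)]), flank=50, bin=10)
        assert np.allclose(pm.matrix[0, :5], [0, 0, 0, 0, 0.1])
        assert np.allclose(pm.matrix[0, 5:], 1.0)

    def test_empty_regions_rejected(self):
        t = track(np.ones(10))
        with pytest.raises(ValueError):
            profile_matrix(t, PeakSet("r", []), flank=50, bin=10)


class TestPromoterPartition:
    tss = TssTable([("chr1", 10_000, "+", "g1")])

    def test_inside_window(self):
        hits = peaks("h", [(12_990, 12_999)])  # TSS + 2,999 inside
        prom, dist = promoter_partition(hits, self.tss, window=3000)
        assert len(prom) == 1 and len(dist) == 0

    def test_outside_window(self):
        hits = peaks("h", [(13_002, 13_050)])  # starts at TSS + 3,002
        prom, dist = promoter_partition(hits, self.tss, window=3000)
        assert len(prom) == 0 and len(dist) == 1

    def test_spanning_edge_is_promoter(self):
        hits = peaks("h", [(12_995, 13_100)])
        prom, dist = promoter_partition(hits, self.tss, window=3000)
        assert len(prom) == 1

    def test_partition_exhaustive(self, rng):
        ivs = [(int(s), int(s) + 100) for s in rng.integers(0, 50_000, 200)]
        hits = peaks("h", ivs)
        prom, dist = promoter_partition(hits, self.tss, window=3000)
        assert len(prom) + len(dist) == len(hits)

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            promoter_partition(peaks("h", [(0, 1)]), TssTable([]), 3000)


class TestMeanSignalAt:
    def test_constant_track(self):
        t = track(np.full(100, 3.0), bin_size=10)
        anchors = TssTable([("chr1", 500, "+", "g")])
        assert np.allclose(mean_signal_at(t, anchors, flank=100), 3.0)

    def test_single_anchor_equals_profile_row(self):
        rng = np.random.default_rng(7)
        t = track(rng.poisson(5, 100).astype(float), bin_size=10)
        anchors = TssTable([("chr1", 500, "+", "g")])
        v = mean_signal_at(t, anchors, flank=100)
        pm = profile_matrix(t, peaks("r", [(499, 501)]), flank=100, bin=10)
        assert np.allclose(v, pm.matrix[0])

    def test_minus_strand_flip(self):
        v = np.zeros(100)
        v[53] = 8.0  # asymmetric signal right of the anchor
        t = track(v, bin_size=10)
        plus = mean_signal_at(t, TssTable([("chr1", 500, "+", "g")]), flank=100)
        # mirrored track: signal equally far left of the anchor
        w = np.zeros(100)
        w[46] = 8.0
        t2 = track(w, bin_size=10)
        minus = mean_signal_at(t2, TssTable([("chr1", 500, "-", "g")]), flank=100)
        assert np.allclose(plus, minus)
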