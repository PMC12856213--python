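"""Motif grammar scanners: worked examples, oracle equivalence, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c4map.seqscan import (
    PQS_CLASSES,
    find_tracts,
    hits_to_peakset,
    revcomp,
    scan_c4,
    scan_pqs,
    scan_units,
)

from .oracles import (
    both_strand_spans,
    chain_spans_oracle,
    unit_spans_oracle,
    window_spans_oracle,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=500)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=300)


def spans(hits):
    return [(h.start, h.end) for h in hits]


def stranded_spans(hits):
    return sorted((h.start, h.end, h.strand) for h in hits)


class TestFindTracts:
    def test_spacer_splits_tracts(self):
        tr = find_tracts("CCCTCCC", "C", 3)
        assert [(t.start, t.end) for t in tr] == [(0, 3), (4, 7)]

    def test_maximality(self):
        tr = find_tracts("CCCCCCC", "C", 3)
        assert [(t.start, t.end) for t in tr] == [(0, 7)]

    def test_wrong_base_no_tracts(self):
        assert find_tracts("GGGG", "C", 3) == []

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            find_tracts("CCC", "C", 0)

    @given(dna)
    def test_runs_are_maximal(self, seq):
        for t in find_tracts(seq, "C", 2):
            assert set(seq[t.start : t.end]) == {"C"}
            assert t.start == 0 or seq[t.start - 1] != "C"
            assert t.end == len(seq) or seq[t.end] != "C"


class TestScanUnits:
    @pytest.mark.parametrize(
        "seq,n",
        [
            ("CCCTCCC", 1),   # central base acts as a spacer
            ("CCTCCC", 0),    # five cytosines in two short tracts: too weak
            ("C" * 7, 1),     # seven consecutive cytosines suffice alone
            ("C" * 6, 0),     # six do not
            ("CCC" + "T" * 8 + "CCC", 0),  # spacer beyond the grammar bound
        ],
    )
    def test_minimal_binding_unit_examples(self, seq, n):
        assert len(scan_units(seq)) == n

    @pytest.mark.parametrize("k", range(1, 9))
    def test_spacer_length_tolerance(self, k):
        hits = scan_units("CCC" + "T" * k + "CCC")
        assert len(hits) == (1 if k <= 7 else 0)

    def test_unit_span(self):
        (h,) = scan_units("CCCTCCC")
        assert (h.start, h.end, h.n_tracts) == (0, 7, 2)

    @given(dna)
    def test_matches_oracle_both_strands(self, seq):
        assert stranded_spans(scan_units(seq)) == both_strand_spans(
            unit_spans_oracle, seq
        )


class TestScanC4:
    def test_telomeric_c_repeat(self):
        (h,) = scan_c4("CCCTAACCCTAACCCTAACCC", 4)
        assert (h.start, h.end) == (0, 21)
        assert h.n_tracts == 4
        assert h.spacer_lengths == (3, 3, 3)

    def test_two_tracts_not_enough_for_four(self):
        assert scan_c4("CCCTCCC", 4) == []

    def test_two_tract_minimum_binds(self):
        (h,) = scan_c4("CCCTCCC", 2)
        assert (h.start, h.end, h.n_tracts) == (0, 7, 2)

    def test_invalid_min_tracts(self):
        with pytest.raises(ValueError):
            scan_c4("CCC", 5)

    def test_n_breaks_a_loop(self):
        assert scan_c4("CCCTNTCCC", 2, strands="+") == []

    @given(dna, st.sampled_from([2, 3, 4]))
    def test_matches_oracle(self, seq, min_tracts):
        got = stranded_spans(scan_c4(seq, min_tracts))
        want = both_strand_spans(
            lambda s: chain_spans_oracle(s, "C", 3, 1, 7, min_tracts), seq
        )
        assert got == want

    @given(dna)
    def test_monotonicity_in_min_tracts(self, seq):
        four = scan_c4(seq, 4)
        two = scan_c4(seq, 2)
        for h in four:
            assert any(
                g.start <= h.start and h.end <= g.end and g.strand == h.strand
                for g in two
            )

    @given(dna_n)
    def test_spacers_within_grammar_and_sorted_nonoverlapping(self, seq):
        hits = scan_c4(seq, 2)
        assert spans(hits) == sorted(spans(hits))
        for strand in "+-":
            sh = [h for h in hits if h.strand == strand]
            for a, b in zip(sh, sh[1:]):
                assert a.end <= b.start
        for h in hits:
            assert all(1 <= s <= 7 for s in h.spacer_lengths)
            assert h.start == h.tracts[0].start and h.end == h.tracts[-1].end


class TestScanPqs:
    def test_telomeric_repeat_canonical(self):
        (h,) = scan_pqs("GGGTTAGGGTTAGGGTTAGGG", "canonical4G")
        assert (h.start, h.end, h.strand, h.n_tracts) == (0, 21, "+", 4)

    def test_strand_duality_of_telomeric_repeat(self):
        seq = "GGGTTAGGGTTAGGGTTAGGG"
        (h,) = scan_pqs(revcomp(seq), "canonical4G")
        assert (h.start, h.end, h.strand) == (0, 21, "-")

    def test_thrombin_aptamer_is_two_quartet_only(self):
        tba = "GGTTGGTGTGGTTGG"
        (h,) = scan_pqs(tba, "twoQuartet")
        assert (h.start, h.end, h.n_tracts) == (0, 15, 4)
        assert scan_pqs(tba, "canonical4G") == []

    def test_long_loop_class_excludes_canonical(self):
        canonical = "GGGTTAGGGTTAGGGTTAGGG"
        assert scan_pqs(canonical, "longLoop15") == []
        long_loop = "GGGTTAGGGTTTTTTTTTGGGTTAGGG"
        (h,) = scan_pqs(long_loop, "longLoop15")
        assert (h.start, h.end) == (0, 27)

    def test_bulged_needs_exactly_one_split_tract(self):
        bulged = "GGTGTTAGGGTTAGGGTTAGGG"  # first tract G2-T-G1... split
        hits = scan_pqs(bulged, "bulged")
        assert len(hits) == 1 and hits[0].start == 0
        assert scan_pqs("GGGTTAGGGTTAGGGTTAGGG", "bulged") == []

    def test_gvbq_one_gg_among_four(self):
        gvbq = "GGGTTAGGTTAGGGTTAGGG"
        (h,) = scan_pqs(gvbq, "GVBQ")
        assert (h.start, h.end) == (0, 20)
        assert scan_pqs("GGGTTAGGGTTAGGGTTAGGG", "GVBQ") == []

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            scan_pqs("GGG", "fancy")

    @given(dna)
    def test_canonical_matches_oracle(self, seq):
        got = stranded_spans(scan_pqs(seq, "canonical4G"))
        want = both_strand_spans(
            lambda s: chain_spans_oracle(s, "G", 3, 1, 7, 4), seq
        )
        assert got == want

    @given(dna)
    def test_two_quartet_matches_oracle(self, seq):
        got = stranded_spans(scan_pqs(seq, "twoQuartet"))
        want = both_strand_spans(
            lambda s: chain_spans_oracle(s, "G", 2, 1, 7, 4), seq
        )
        assert got == want

    @settings(max_examples=30)
    @given(st.text(alphabet="ACGT", max_size=200), st.sampled_from(["GVBQ", "longLoop15", "bulged"]))
    def test_window_classes_match_oracle(self, seq, cls):
        got = stranded_spans(scan_pqs(seq, cls))
        want = both_strand_spans(lambda s: window_spans_oracle(s, cls), seq)
        assert got == want

    @given(dna)
    def test_c4_pqs_strand_duality(self, seq):
        c4 = stranded_spans(scan_c4(seq, 4))
        n = len(seq)
        mirrored = sorted(
            (n - e, n - s, {"+": "-", "-": "+"}[strand])
            for s, e, strand in stranded_spans(scan_pqs(revcomp(seq), "canonical4G"))
        )
        assert c4 == mirrored


class TestHitsToPeakset:
    def test_offset_applied(self):
        hits = scan_c4("CCCTAACCCTAACCCTAACCC", 4)
        ps = hits_to_peakset(hits, "chr7", offset=100)
        iv = ps.intervals[0]
        assert (iv.chrom, iv.start, iv.end) == ("chr7", 100, 121)
        assert iv.name == "C4" and iv.score == 4.0

    def test_empty_hits(self):
        assert len(hits_to_peakset([], "chr1")) == 0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            hits_to_peakset([], "chr1", offset=-1)

    def test_two_hits_sorted(self):
        seq = "CCCTCCC" + "A" * 30 + "CCCTCCC"
        ps = hits_to_peakset(scan_c4(seq, 2), "chr1")
        starts = [iv.start for iv in ps]
        assert starts == sorted(starts) and len(ps) == 2
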