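import pytest
from hypothesis import given
from hypothesis import strategies as st

from duplexkit.consensus import (
    SSCS,
    call_column,
    call_dcs,
    call_sscs,
    gap_quality,
    iupac_pair,
    route_unpaired_sscs,
    trim_ambiguous,
)
from duplexkit.msa import GAP_QUAL_PLACEHOLDER, AlignedFamily


def _fam(rows, qual=40):
    qc = chr(qual + 33)
    quals = [
        "".join(GAP_QUAL_PLACEHOLDER if c == "-" else qc for c in row) for row in rows
    ]
    return AlignedFamily(rows, quals, [f"r{i}" for i in range(len(rows))])


class TestCallColumn:
    def test_two_thirds_majority(self):
        assert call_column(["A", "A", "G"], [30, 30, 30]) == "A"

    def test_even_split_is_n(self):
        assert call_column(["A", "G"], [30, 30]) == "N"

    def test_quality_filter_changes_the_vote(self):
        # both A's fail the filter, so the lone counted G wins
        assert call_column(["A", "A", "G"], [10, 10, 30], qual_thresh=20) == "G"

    def test_nothing_counted_is_n(self):
        assert call_column(["A", "A"], [5, 5], qual_thresh=20) == "N"

    def test_gaps_vote_like_bases(self):
        assert call_column(["-", "-", "A"], [30, 30, 30]) == "-"

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            call_column([], [])

    @given(
        st.lists(st.sampled_from("ACGT-"), min_size=1, max_size=7),
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=45),
    )
    def test_equal_qualities_threshold_monotone(self, bases, q, thresh):
        """With uniform qualities, raising the threshold never turns N into a base."""
        quals = [q] * len(bases)
        lo = call_column(bases, quals, qual_thresh=thresh)
        hi = call_column(bases, quals, qual_thresh=thresh + 5)
        if lo == "N":
            assert hi == "N"


class TestGapQuality:
    def test_constant_neighbors(self):
        row = [30] * 4 + [None] + [30] * 4
        assert gap_quality(row, 4) == 30.0

    def test_mirror_symmetric_sides_average(self):
        # the two sides are 20/40 mirrors of each other, so rank-weighted
        # contributions pair up to 60 at every distance
        row = [40, 20, 40, 20, None, 40, 20, 40, 20]
        assert gap_quality(row, 4) == 30.0

    def test_linear_weights_hand_computed(self):
        # nearest-to-farthest 40,30,20,10 on each side:
        # (4*40 + 3*30 + 2*20 + 1*10) * 2 / (2 * (4+3+2+1)) = 600/20 = 30
        row = [10, 20, 30, 40, None, 40, 30, 20, 10]
        assert gap_quality(row, 4) == 30.0

    def test_end_of_read_renormalises(self):
        # only a right side: weights 4,3 on qualities 10, 20
        row = [None, 10, 20]
        assert gap_quality(row, 0) == pytest.approx((4 * 10 + 3 * 20) / 7)

    def test_no_real_bases_scores_zero(self):
        assert gap_quality([None, None, None], 1) == 0.0

    def test_accepts_sanger_strings(self):
        row = "II" + GAP_QUAL_PLACEHOLDER + "II"
        assert gap_quality(row, 2) == 40.0


class TestCallSSCS:
    def test_identity(self):
        sscs = call_sscs(_fam(["ACGT"] * 3))
        assert sscs.seq == "ACGT"
        assert sscs.n_reads == 3

    def test_below_min_reads_is_none(self):
        assert call_sscs(_fam(["ACGT"] * 2)) is None

    def test_gap_column_outvoted_and_removed(self):
        sscs = call_sscs(_fam(["ACGT", "A-GT", "ACGT"]))
        assert sscs.seq == "ACGT"

    def test_majority_gap_column_dropped(self):
        sscs = call_sscs(_fam(["A-GT", "A-GT", "ACGT"]))
        assert sscs.seq == "AGT"

    def test_split_column_is_n(self):
        sscs = call_sscs(_fam(["ACGT", "ACGT", "AAGT", "AAGT"]), min_reads=4)
        assert sscs.seq == "ANGT"


class TestIupacPair:
    @pytest.mark.parametrize(
        "pair,expect",
        [
            (("A", "A"), "A"),
            (("A", "G"), "R"),
            (("C", "T"), "Y"),
            (("G", "C"), "S"),
            (("A", "T"), "W"),
            (("G", "T"), "K"),
            (("A", "C"), "M"),
            (("A", "-"), "N"),
            (("-", "-"), "N"),
            (("N", "A"), "N"),
            (("N", "N"), "N"),
        ],
    )
    def test_table(self, pair, expect):
        assert iupac_pair(*pair) == expect

    @given(st.sampled_from("ACGTN-"), st.sampled_from("ACGTN-"))
    def test_symmetric(self, x, y):
        assert iupac_pair(x, y) == iupac_pair(y, x)

    def test_invalid_char_rejected(self):
        with pytest.raises(ValueError):
            iupac_pair("A", "Z")


def _sscs(seq, order="AB", mate=1, n=3, bc="X" * 24):
    return SSCS(bc, order, mate, seq, n)


class TestCallDCS:
    def test_identical_sscs(self):
        dcs = call_dcs(_sscs("ACGT"), _sscs("ACGT", order="BA", mate=2))
        assert dcs.seq == "ACGT"
        assert (dcs.n_reads_ab, dcs.n_reads_ba) == (3, 3)

    def test_substitution_becomes_iupac(self):
        dcs = call_dcs(_sscs("ACGTACGT"), _sscs("ACATACGT", order="BA"))
        assert dcs.seq == "ACRTACGT"

    def test_indel_column_becomes_n(self):
        dcs = call_dcs(_sscs("ACGTTTACGTAC"), _sscs("ACGTTACGTAC", order="BA"))
        assert "N" in dcs.seq
        assert dcs.seq.replace("N", "", 1) in ("ACGTTACGTAC",)

    def test_empty_sscs_gives_none(self):
        assert call_dcs(_sscs(""), _sscs("ACGT", order="BA")) is None

    def test_mismatched_barcodes_rejected(self):
        with pytest.raises(ValueError):
            call_dcs(_sscs("ACGT", bc="A" * 24), _sscs("ACGT", bc="C" * 24))


class TestUnpairedPolicy:
    def test_policies(self):
        s = _sscs("ACGT")
        assert route_unpaired_sscs(s, "include") == "main"
        assert route_unpaired_sscs(s, "separate") == "sscs"
        assert route_unpaired_sscs(s, "discard") is None

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            route_unpaired_sscs(_sscs("ACGT"), "bogus")


class TestTrimAmbiguous:
    def test_clean_sequence_unchanged(self):
        assert trim_ambiguous("ACGT", "trim") == "ACGT"
        assert trim_ambiguous("ACGT", "remove") == "ACGT"

    def test_leading_ns_trimmed(self):
        assert trim_ambiguous("NNNNACGTACGT", "trim") == "ACGTACGT"

    def test_trailing_ns_trimmed(self):
        assert trim_ambiguous("ACGTACGTNNNN", "trim") == "ACGTACGT"

    def test_remove_drops_ambiguous_sequence(self):
        assert trim_ambiguous("N" * 10, "remove") is None
        assert trim_ambiguous("ACGTNNNNNN", "remove", max_frac_n=0.3) is None

    def test_remove_keeps_mostly_clean(self):
        seq = "ACGTACGTACGTACGTACGN"
        assert trim_ambiguous(seq, "remove", max_frac_n=0.3) == seq

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            trim_ambiguous("ACGT", "chop")
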