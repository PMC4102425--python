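"""Junction decomposition: worked examples, round trips, enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nhejscar import (
    CallParams,
    CutReference,
    DetectionWindow,
    JunctionRead,
    UnalignableReadError,
    anchor_read,
    batch_analyze,
    call_junction,
    reconstruct_read,
)
from nhejscar.caller import InconsistentEventError, _lcp, _lcs, parse_read_id
from tests.conftest import random_flanks


def oracle_decompose(read: str, left: str, right: str):
    """Independent oracle: enumerate every decomposition read = prefix(left)
    + insertion + suffix(right); minimize insertion length, tie-break
    left-greedy.  Microhomology = (#zero-insertion decompositions) - 1."""

    def matches(x: str, y: str) -> bool:
        return len(x) == len(y) and all(a == b != "N" for a, b in zip(x, y))

    n = len(read)
    A = [a for a in range(n + 1) if a <= len(left) and matches(read[:a], left[:a])]
    B = [
        b
        for b in range(n + 1)
        if b <= len(right) and matches(read[n - b :], right[len(right) - b :])
    ]
    zero_ins = [(a, b) for a in A for b in B if a + b == n]
    a_max, b_max = max(A), max(B)
    if zero_ins:
        return a_max, b_max, len(zero_ins) - 1, ""
    best = min(n - a - b for a in A for b in B if a + b <= n)
    a = max(a for a in A for b in B if a + b <= n and n - a - b == best)
    b = n - a - best
    return a_max, b_max, 0, read[a : a + best]


def assert_matches_oracle(read_seq, cutref):
    ev = call_junction(JunctionRead(id="r", sequence=read_seq), cutref)
    a, b, mh, ins = oracle_decompose(read_seq, cutref.left_flank, cutref.right_flank)
    assert (ev.left_match, ev.right_match, ev.mh_len, ev.insertion_seq) == (a, b, mh, ins)
    assert reconstruct_read(ev, cutref) == read_seq


class TestWorkedExamples:
    """Flanks ACGTCAT / CATGGA: the shared CAT creates a 3-bp microhomology."""

    def test_microhomology_junction(self, toy_cutref):
        ev = call_junction(JunctionRead(id="r", sequence="ACGTCATGGA"), toy_cutref)
        assert (ev.left_match, ev.right_match) == (7, 6)
        assert ev.mh_len == 3 and ev.insertion_len == 0
        assert ev.del_total == 3
        assert ev.ambiguity == 3
        assert ev.event_class == "deletion"

    def test_insertion_junction(self, toy_cutref):
        ev = call_junction(JunctionRead(id="r", sequence="ACGTCATTTCATGGA"), toy_cutref)
        assert (ev.left_match, ev.right_match) == (7, 6)
        assert ev.insertion_seq == "TT" and ev.mh_len == 0
        assert ev.del_total == 0
        assert ev.event_class == "insertion"

    def test_perfect_rejoining(self, toy_cutref):
        read = toy_cutref.left_flank + toy_cutref.right_flank
        ev = call_junction(JunctionRead(id="r", sequence=read), toy_cutref)
        assert ev.event_class == "exact"
        assert ev.del_total == ev.insertion_len == ev.mh_len == 0

    def test_examples_agree_with_oracle(self, toy_cutref):
        for read in ("ACGTCATGGA", "ACGTCATTTCATGGA", "ACGTCATCATGGA"):
            assert_matches_oracle(read, toy_cutref)

    @pytest.mark.parametrize("mh,expected", [(4, False), (5, True), (16, True), (25, True), (26, False)])
    def test_mmej_classification_boundary(self, mh, expected):
        # homopolymer flanks force an exact target microhomology
        L = 30
        ref = CutReference("A" * L, "A" * L, L)
        # deletion junction with span mh: read shorter by mh bases
        read = "A" * (2 * L - mh)
        ev = call_junction(JunctionRead(id="r", sequence=read), ref)
        assert ev.mh_len == mh
        assert ev.is_mmej is expected


class TestReconstruct:
    def test_exact_event_reconstruction(self, toy_cutref):
        ev = call_junction(
            JunctionRead(id="r", sequence=toy_cutref.joined), toy_cutref
        )
        assert reconstruct_read(ev, toy_cutref) == "ACGTCAT" + "CATGGA"

    def test_mh_and_insertion_examples_round_trip(self, toy_cutref):
        for read in ("ACGTCATGGA", "ACGTCATTTCATGGA"):
            ev = call_junction(JunctionRead(id="r", sequence=read), toy_cutref)
            assert reconstruct_read(ev, toy_cutref) == read

    def test_inconsistent_event_rejected(self, toy_cutref):
        ev = call_junction(JunctionRead(id="r", sequence="ACGTCATGGA"), toy_cutref)
        ev.insertion_seq, ev.insertion_len = "GG", 2  # mh_len is still 3
        with pytest.raises(InconsistentEventError):
            reconstruct_read(ev, toy_cutref)


class TestUnalignableAndFlags:
    def test_no_left_match_rejected(self, toy_cutref):
        with pytest.raises(UnalignableReadError):
            call_junction(JunctionRead(id="r", sequence="TTTTCATGGA"), toy_cutref)

    def test_no_right_match_rejected(self, toy_cutref):
        with pytest.raises(UnalignableReadError):
            call_junction(JunctionRead(id="r", sequence="ACGTCATCCC"), toy_cutref)

    def test_outside_window_flagged_not_rejected(self, toy_cutref):
        params = CallParams(window=DetectionWindow(1, 1))
        ev = call_junction(JunctionRead(id="r", sequence="ACGTCATGGA"), toy_cutref, params)
        assert ev.outside_window  # 3 bp deleted on the right exceeds max 1

    def test_n_terminates_extension(self, toy_cutref):
        ev = call_junction(JunctionRead(id="r", sequence="ACGNCATGGA"), toy_cutref)
        assert ev.left_match == 3
        assert_matches_oracle("ACGNCATGGA", toy_cutref)


class TestBatchAndDedupe:
    def _reads(self, seqs, reactions):
        return [
            JunctionRead(id=f"c|m1|{rx}|c{i}", sequence=s, source_reaction=rx)
            for i, (s, rx) in enumerate(zip(seqs, reactions))
        ]

    def test_identical_reads_same_reaction_collapse(self, toy_cutref):
        reads = self._reads(["ACGTCATGGA", "ACGTCATGGA"], ["r1", "r1"])
        events, rejects, info = batch_analyze(reads, toy_cutref)
        assert len(events) == 1
        assert info["n_duplicates_dropped"] == 1

    def test_identical_reads_different_reactions_kept(self, toy_cutref):
        reads = self._reads(["ACGTCATGGA", "ACGTCATGGA"], ["r1", "r2"])
        events, _, info = batch_analyze(reads, toy_cutref)
        assert len(events) == 2 and info["n_duplicates_dropped"] == 0

    def test_distinct_junctions_same_reaction_kept(self, toy_cutref):
        reads = self._reads(["ACGTCATGGA", "ACGTCATTTCATGGA"], ["r1", "r1"])
        events, _, _ = batch_analyze(reads, toy_cutref)
        assert len(events) == 2

    def test_unalignable_reads_recorded_as_rejects(self, toy_cutref):
        reads = self._reads(["ACGTCATGGA", "TTTTTTTTTT"], ["r1", "r2"])
        events, rejects, info = batch_analyze(reads, toy_cutref)
        assert len(events) == 1 and len(rejects) == 1
        assert info["n_unalignable"] == 1

    def test_read_id_parsing(self):
        fields = parse_read_id("lung_old|m3|r17|c2")
        assert fields == {"cohort": "lung_old", "mouse": "m3", "reaction": "r17", "clone": "c2"}
        assert parse_read_id("only")["reaction"] is None


class TestPrimerAnchoring:
    def test_amplicon_maps_to_flank_coordinates(self, small_assay):
        construct, cutref, window = small_assay
        from nhejscar.construct import reverse_complement

        left, right = cutref.left_flank, cutref.right_flank
        # amplicon: forward primer .. junction .. revcomp(reverse primer)
        fstart = left.find(construct.primer_fwd)
        rc = reverse_complement(construct.primer_rev)
        rend = right.find(rc) + len(rc)
        amplicon = left[fstart : len(left) - 5] + right[3:rend]
        read = anchor_read(
            JunctionRead(id="a", sequence=amplicon), construct, cutref
        )
        ev = call_junction(read, cutref, CallParams(window=window))
        assert ev.del_total == 8  # 5 bp lost left of the cut + 3 bp right
        assert not ev.outside_window

    def test_flank_anchored_read_unchanged(self, small_assay):
        construct, cutref, _ = small_assay
        r = JunctionRead(id="a", sequence=cutref.joined)
        assert anchor_read(r, construct, cutref) is r


class TestMatchPrimitives:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGA", 3), ("", "ACG", 0), ("ACG", "ACG", 3), ("AANG", "AANG", 2)],
    )
    def test_lcp(self, a, b, expected):
        assert _lcp(a, b) == expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [("TACG", "GACG", 3), ("ACG", "ACG", 3), ("GNCG", "GNCG", 2), ("", "A", 0)],
    )
    def test_lcs(self, a, b, expected):
        assert _lcs(a, b) == expected


class TestProperties:
    @settings(derandomize=True, max_examples=200)
    @given(
        seed=st.integers(0, 10_000),
        d5=st.integers(0, 10),
        d3=st.integers(0, 10),
        ins=st.text(alphabet="ACGT", max_size=8),
    )
    def test_roundtrip_on_random_synthetic_reads(self, seed, d5, d3, ins):
        rng = np.random.default_rng(seed)
        cutref = random_flanks(rng, 20, 20)
        read = cutref.left_flank[: 20 - d5] + ins + cutref.right_flank[d3:]
        ev = call_junction(JunctionRead(id="r", sequence=read), cutref)
        assert reconstruct_read(ev, cutref) == read
        assert ev.mh_len <= ev.del_total
        assert_matches_oracle(read, cutref)

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(0, 10_000),
        d5=st.integers(1, 8),
        d3=st.integers(1, 8),
        extra=st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    def test_appending_insertion_bases_is_monotone(self, seed, d5, d3, extra):
        """Growing a read's insertion never shrinks insertion_len or alters mh."""
        rng = np.random.default_rng(seed)
        cutref = random_flanks(rng, 25, 25)
        left, right = cutref.left_flank, cutref.right_flank
        # boundary-safe seed insertion so the base read is an insertion event
        first = next(b for b in "ACGT" if b != left[25 - d5])
        last = next(b for b in "ACGT" if b != right[d3 - 1])
        ins = first + last
        base = left[: 25 - d5] + ins + right[d3:]
        grown = left[: 25 - d5] + ins[:-1] + extra + ins[-1] + right[d3:]
        ev0 = call_junction(JunctionRead(id="r", sequence=base), cutref)
        ev1 = call_junction(JunctionRead(id="r", sequence=grown), cutref)
        assert ev1.insertion_len >= ev0.insertion_len
        assert ev1.mh_len == ev0.mh_len == 0
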