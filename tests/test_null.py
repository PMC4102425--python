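"""Random-joining null: per-pair MH oracles, enumeration, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from nhejscar import (
    CutReference,
    DetectionWindow,
    JunctionRead,
    apparent_mh,
    call_junction,
    junction_mh,
    longest_mh,
    mh_excess_test,
    random_joining_distribution,
)
from nhejscar.null import EmptyWindowError, NotADeletionJunctionError
from tests.conftest import random_flanks


def naive_apparent_mh(i, j, ref):
    """k-loop oracle: largest k with ref[i-k+1..i] == ref[j-k..j-1] (1-based)."""
    span = j - i - 1
    for k in range(min(i, span), -1, -1):
        a, b = ref[i - k : i], ref[j - 1 - k : j - 1]
        if a == b and "N" not in a:
            return k
    return 0


class TestApparentMH:
    def test_worked_example_shared_aac(self):
        # both windows read AAC
        assert apparent_mh(4, 10, "TAACGGAACTT") == 3

    def test_zero_span_forces_zero(self):
        for ref in ("ACGTACGT", "AAAAAAAA"):
            for i in range(1, len(ref)):
                assert apparent_mh(i, i + 1, ref) == 0

    def test_homopolymer_gives_deleted_span(self):
        ref = "A" * 12
        for i in range(2, 8):
            for j in range(i + 2, 12):
                assert apparent_mh(i, j, ref) == min(i, j - i - 1)

    def test_not_a_deletion_junction_rejected(self):
        with pytest.raises(NotADeletionJunctionError):
            apparent_mh(5, 5, "ACGTACGT")

    def test_exhaustive_agreement_with_naive_oracle(self):
        rng = np.random.default_rng(42)
        refs = [
            "".join(rng.choice(list("ACGT"), n)) for n in (10, 25, 50)
        ] + ["A" * 20, "ACGT" * 12, "TTAACGGAACTTAACG"]
        for ref in refs:
            for i in range(1, len(ref) + 1):
                for j in range(i + 1, len(ref) + 2):
                    assert apparent_mh(i, j, ref) == naive_apparent_mh(i, j, ref)


class TestJunctionMHEqualsCaller:
    """The per-pair MH used by the null must be what the caller reports."""

    @pytest.mark.parametrize("seed", range(6))
    def test_all_pairs_on_random_flanks(self, seed):
        rng = np.random.default_rng(seed)
        cutref = random_flanks(rng, 18, 15)
        ref, cut = cutref.joined, cutref.cut_coordinate
        # rescuable pairs keep >= 1 bp of each flank, as the null enumeration does
        for i in range(1, cut + 1):
            for j in range(cut + 1, len(ref) + 1):
                if i == cut and j == cut + 1:
                    continue
                read = ref[:i] + ref[j - 1 :]
                ev = call_junction(JunctionRead(id="r", sequence=read), cutref)
                assert junction_mh(i, j, ref, cut) == ev.mh_len, (i, j, ref)

    def test_homopolymer_pairs(self):
        cutref = CutReference("A" * 10, "A" * 10, 10)
        ref = cutref.joined
        for i in range(1, 11):
            for j in range(11, 21):
                if (i, j) == (10, 11):
                    continue
                read = ref[:i] + ref[j - 1 :]
                ev = call_junction(JunctionRead(id="r", sequence=read), cutref)
                assert junction_mh(i, j, ref, 10) == ev.mh_len


def brute_force_distribution(cutref, window):
    """Second, independently coded enumeration: build every junction read and
    decompose it by exhaustive search (no shared code with the null)."""
    from tests.test_caller import oracle_decompose

    left, right = cutref.left_flank, cutref.right_flank
    cut = cutref.cut_coordinate
    ref = left + right
    counts = {}
    n = 0
    for d5 in range(0, window.max_del_5prime + 1):
        for d3 in range(0, window.max_del_3prime + 1):
            if d5 == 0 and d3 == 0:
                continue
            read = ref[: cut - d5] + ref[cut + d3 :]
            _, _, mh, ins = oracle_decompose(read, left, right)
            assert ins == ""
            counts[mh] = counts.get(mh, 0) + 1
            n += 1
    return {m: c / n for m, c in counts.items()}, n


class TestRandomJoiningDistribution:
    def test_homopolymer_every_deletion_junction_has_mh(self):
        cutref = CutReference("AAAA", "AAAA", 4)
        dist = random_joining_distribution(cutref)
        assert dist.p_mh_ge[1] == 1.0

    def test_agrees_exactly_with_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(4):
            cutref = random_flanks(rng, 14, 12)
            window = DetectionWindow(9, 8)
            dist = random_joining_distribution(cutref, window)
            brute, n = brute_force_distribution(cutref, window)
            assert dist.n_pairs == n
            assert set(dist.probs) == set(brute)
            for m, p in brute.items():
                assert dist.probs[m] == pytest.approx(p, abs=0)

    def test_enumeration_completeness(self, small_assay):
        _, cutref, window = small_assay
        dist = random_joining_distribution(cutref, window)
        expected = (window.max_del_5prime + 1) * (window.max_del_3prime + 1) - 1
        assert dist.n_pairs == expected
        with_blunt = random_joining_distribution(cutref, window, include_blunt=True)
        assert with_blunt.n_pairs == expected + 1

    def test_normalization_and_monotonicity(self, small_assay):
        _, cutref, window = small_assay
        for mode in ("junction", "anchored"):
            dist = random_joining_distribution(cutref, window, mode=mode)
            assert sum(dist.probs.values()) == pytest.approx(1.0, abs=1e-12)
            ks = sorted(dist.p_mh_ge)
            assert all(dist.p_mh_ge[a] >= dist.p_mh_ge[b] for a, b in zip(ks, ks[1:]))
            assert dist.p_mh_ge[1] == pytest.approx(1 - dist.probs.get(0, 0.0))
            assert dist.max_mh == max(m for m, p in dist.probs.items() if p > 0)

    def test_homopolymer_closed_form(self):
        # all-A flanks with spans bounded by min flank length: MH == deleted span,
        # so probs[m] is exactly the fraction of pairs with span m.
        L = R = 12
        w = DetectionWindow(6, 6)
        dist = random_joining_distribution(CutReference("A" * L, "A" * R, L), w)
        n_pairs = 7 * 7 - 1
        span_counts = {}
        for d5 in range(7):
            for d3 in range(7):
                if d5 == d3 == 0:
                    continue
                span_counts[d5 + d3] = span_counts.get(d5 + d3, 0) + 1
        for m, c in span_counts.items():
            assert dist.probs[m] == pytest.approx(c / n_pairs, abs=0)

    def test_empty_window_rejected(self, toy_cutref):
        with pytest.raises(EmptyWindowError):
            random_joining_distribution(toy_cutref, DetectionWindow(0, 0))


class TestLongestMH:
    def test_homopolymer_bounded_by_window(self):
        # window (3,3): MH = span is capped at 3 + 3; full window: the all-A
        # read of length 9 (span 9) is ambiguous over its whole length
        cutref = CutReference("A" * 9, "A" * 9, 9)
        assert longest_mh(cutref, DetectionWindow(3, 3)) == 6
        assert longest_mh(cutref) == 9

    def test_planted_repeat_is_longest(self, repeat_assay):
        _, cutref, window = repeat_assay
        assert longest_mh(cutref, window) == 7


class TestMHExcess:
    def _events(self, mhs):
        return pd.DataFrame({"mh_len": mhs})

    def test_observed_equal_to_null_gives_p_one(self, small_assay):
        _, cutref, window = small_assay
        dist = random_joining_distribution(cutref, window)
        p1 = dist.p_mh_ge[1]
        n = 200
        x = round(p1 * n)
        events = self._events([1] * x + [0] * (n - x))
        res = mh_excess_test(events, dist, k_min=1)
        # x is rounded to an integer count, so the statistic is only near 0
        assert abs(res.statistic) < 0.15
        assert res.p_value > 0.85

    def test_hand_checked_one_proportion_statistic(self, small_assay):
        """30 junctions all with MH >= 1 against an expected 44%."""
        _, cutref, window = small_assay
        dist = random_joining_distribution(cutref, window)
        res = mh_excess_test(self._events([2] * 30), dist, k_min=1)
        p0 = dist.p_mh_ge[1]
        expected = (1 - p0) / math.sqrt(p0 * (1 - p0) / 30)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_kmin_beyond_max_mh_degenerates(self, small_assay):
        _, cutref, window = small_assay
        dist = random_joining_distribution(cutref, window)
        res = mh_excess_test(self._events([0, 1, 2]), dist, k_min=dist.max_mh + 1)
        assert res.degenerate and res.p_value == 1.0
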