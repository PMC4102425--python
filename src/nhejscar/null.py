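"""Random end-joining null model for apparent microhomology.

If two break ends are joined at a random pair of breakpoints within the
intron, short identical stretches in the flanking sequence will often make
the junction *look* microhomology-mediated.  This module enumerates every
rescuable breakpoint pair, computes the apparent microhomology each pair
would display, and tabulates the resulting distribution -- the "expected by
chance" baseline against which observed junction calls are compared.

Two per-pair microhomology definitions are provided:

``junction`` (default)
    Exactly what the junction caller reports for the read produced by the
    pair (i, j): with d5/d3 the per-side deletions and e_fwd/e_back the
    forward/backward repeat extensions at the breakpoints,
    ``mh = min(e_fwd, d5) + min(e_back, d3)``.  Using this mode, the null and
    the observed calls measure the same quantity, so a cohort of junctions
    simulated by uniform random joining reproduces the null exactly.

``anchored``
    The backward-only extension :func:`apparent_mh` (the repeat stretch
    immediately 5' of each breakpoint), a common anchored convention; kept
    for comparison but not what the caller reports.

Coordinates follow the joined reference ``left_flank + right_flank``
(1-based): a pair (i, j) retains positions [1, i] and [j, end].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .construct import CutReference, DetectionWindow
from .stats import TestResult, one_proportion_test


class NotADeletionJunctionError(ValueError):
    """apparent_mh requires j > i (a deletion junction)."""


class EmptyWindowError(ValueError):
    """The detection window admits no breakpoint pairs."""


def apparent_mh(i: int, j: int, ref: str) -> int:
    """Backward-anchored apparent microhomology of the junction (i, j).

    Largest ``k <= j - i - 1`` with ``ref[i-k+1..i] == ref[j-k..j-1]``
    (1-based closed intervals); bounded by the deleted span so microhomology
    never exceeds deletion size.  ``N`` never matches.
    """
    if j <= i:
        raise NotADeletionJunctionError(f"need j > i, got i={i}, j={j}")
    if i < 1 or j > len(ref) + 1:
        raise ValueError(f"(i={i}, j={j}) outside reference of length {len(ref)}")
    span = j - i - 1
    kmax = min(i, span)
    k = 0
    while k < kmax:
        x, y = ref[i - 1 - k], ref[j - 2 - k]
        if x != y or x == "N":
            break
        k += 1
    return k


def _forward_mh(i: int, j: int, ref: str) -> int:
    """Forward repeat extension: largest k with ref[j..j+k-1] == ref[i+1..i+k]."""
    span = j - i - 1
    kmax = min(len(ref) - j + 1, span)
    k = 0
    while k < kmax:
        x, y = ref[j - 1 + k], ref[i + k]
        if x != y or x == "N":
            break
        k += 1
    return k


def junction_mh(i: int, j: int, ref: str, cut: int) -> int:
    """Caller-consistent microhomology of the junction (i, j).

    ``cut`` is the joined-reference coordinate of the cut (= len(left_flank));
    requires ``i <= cut < j``.  Equals the ``mh_len`` the junction caller
    reports for the read ``ref[1..i] + ref[j..end]`` (verified in tests).
    """
    if j <= i:
        raise NotADeletionJunctionError(f"need j > i, got i={i}, j={j}")
    if not (i <= cut <= j - 1):
        raise ValueError(f"cut {cut} must satisfy i <= cut < j (i={i}, j={j})")
    d5 = cut - i
    d3 = j - cut - 1
    if d5 == 0 and d3 == 0:
        return 0
    e_back = apparent_mh(i, j, ref)
    e_fwd = _forward_mh(i, j, ref)
    return min(e_fwd, d5) + min(e_back, d3)


@dataclass(frozen=True)
class MHNullDistribution:
    """Distribution of apparent microhomology under uniform random joining."""

    probs: dict[int, float]
    n_pairs: int
    p_mh_ge: dict[int, float] = field(default_factory=dict)
    max_mh: int = 0

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        ks = sorted(self.p_mh_ge)
        for lo, hi in zip(ks, ks[1:]):
            if self.p_mh_ge[hi] > self.p_mh_ge[lo] + 1e-12:
                raise ValueError("p_mh_ge must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        ms = sorted(self.probs)
        return pd.DataFrame(
            {
                "mh": ms,
                "prob": [self.probs[m] for m in ms],
                "p_mh_ge": [self.p_mh_ge[m] for m in ms],
            }
        )


def random_joining_distribution(
    cutref: CutReference,
    window: Optional[DetectionWindow] = None,
    include_blunt: bool = False,
    mode: str = "junction",
) -> MHNullDistribution:
    """Exhaustively enumerate breakpoint pairs and tabulate apparent MH.

    Pairs are weighted uniformly ("joined at random"): i ranges over left
    breakpoints within ``max_del_5prime`` of the cut, j over right breakpoints
    within ``max_del_3prime``; one-sided deletions are included.  The
    zero-deletion blunt pair is excluded by default because apparent
    microhomology is undefined without a deleted span.  ``window=None``
    enumerates the whole intron (full-flank mode).  Deterministic.
    """
    if mode not in ("junction", "anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    left, right = cutref.left_flank, cutref.right_flank
    cut = cutref.cut_coordinate
    ref = left + right
    if window is None:
        max5, max3 = len(left) - 1, len(right) - 1
    else:
        max5 = min(window.max_del_5prime, len(left) - 1)
        max3 = min(window.max_del_3prime, len(right) - 1)
    counts: dict[int, int] = {}
    n_pairs = 0
    for i in range(cut - max5, cut + 1):
        for j in range(cut + 1, cut + 2 + max3):
            if i == cut and j == cut + 1 and not include_blunt:
                continue
            if mode == "junction":
                m = junction_mh(i, j, ref, cut)
            else:
                m = apparent_mh(i, j, ref)
            counts[m] = counts.get(m, 0) + 1
            n_pairs += 1
    if n_pairs == 0:
        raise EmptyWindowError("detection window admits no breakpoint pairs")
    probs = {m: c / n_pairs for m, c in sorted(counts.items())}
    max_mh = max(probs)
    p_ge: dict[int, float] = {}
    running = 0.0
    for m in range(max_mh, -1, -1):
        running += probs.get(m, 0.0)
        p_ge[m] = min(running, 1.0)
    p_ge = dict(sorted(p_ge.items()))
    return MHNullDistribution(probs=probs, n_pairs=n_pairs, p_mh_ge=p_ge, max_mh=max_mh)


def longest_mh(
    cutref: CutReference,
    window: Optional[DetectionWindow] = None,
    mode: str = "junction",
) -> int:
    """Longest apparent microhomology achievable within the window."""
    return random_joining_distribution(cutref, window, mode=mode).max_mh


def mh_excess_test(
    observed_events: pd.DataFrame,
    null: MHNullDistribution,
    k_min: int = 1,
) -> TestResult:
    """Test the observed MH >= k_min fraction against the random-joining null.

    One-sample test on a percent: the null probability ``p_mh_ge[k_min]`` is
    treated as a fixed proportion and the observed fraction compared via the
    one-proportion z statistic (two-sided normal p).  If ``k_min`` exceeds the
    longest achievable microhomology the expected fraction is 0 and the test
    degenerates (flagged).
    """
    n = len(observed_events)
    if n < 1:
        raise ValueError("need at least one observed event")
    x = int((observed_events["mh_len"] >= k_min).sum())
    p0 = null.p_mh_ge.get(k_min, 0.0)
    return one_proportion_test(x, n, p0)
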