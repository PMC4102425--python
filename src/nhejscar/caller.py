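"""Junction calling: infer each read's repair signature against the cut reference.

A repair junction read is decomposed as

    read = left_flank[1..a] + insertion + right_flank[(R-b+mh)+1..R]

where ``a`` is the maximal end-anchored prefix match against the left flank,
``b`` the maximal suffix match against the right flank, and, when the two
matches overlap (a + b > len(read)), the overlap is the junction's apparent
microhomology ``mh``.  The decomposition is canonicalized left-greedily:
microhomology bases are attributed to the left flank, so deletion on the 5'
side is ``len(left_flank) - a`` and the microhomology span counts toward the
3'-side deletion.  ``del_total`` is always the number of reference bases
absent from the read and is invariant under the attribution choice; the
``ambiguity`` field (= mh) records how far the breakpoint could slide.

Matching is exact by default (Sanger-sequenced clones); ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

from .construct import CutReference, DetectionWindow, ReporterConstruct

EVENT_CLASSES = ("exact", "deletion", "insertion", "deletion+insertion")


class UnalignableReadError(ValueError):
    """The read does not match either flank at >= 1 bp on one side."""


class InconsistentEventError(ValueError):
    """A repair event's fields violate the decomposition contract."""


@dataclass(frozen=True)
class JunctionRead:
    """One Sanger-sequenced cloned repair product.

    Read ids of the form ``cohort|mouse|reaction|clone`` are parsed by
    :func:`parse_read_id`; ``source_reaction`` identifies the PCR reaction of
    origin for the one-unique-junction-per-reaction rule.
    """

    id: str
    sequence: str
    source_reaction: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id!r} has non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class CallParams:
    """Parameters of junction calling and MMEJ classification.

    ``mmej_min``/``mmej_max``: junction microhomology range (bp) classified as
    microhomology-mediated end joining; MMEJ characteristically uses roughly
    5-25 bp of homology, hence the defaults.  ``max_mismatch`` > 0 enables a
    mismatch-tolerant extension mode for noisy reads (off by default; the
    exact round-trip guarantee holds only at 0).
    """

    mmej_min: int = 5
    mmej_max: int = 25
    max_mismatch: int = 0
    window: Optional[DetectionWindow] = None
    detect_ad_retention: bool = False
    ad_kmer: int = 16

    def __post_init__(self) -> None:
        if self.mmej_min < 1:
            raise ValueError("mmej_min must be >= 1")
        if self.mmej_min > self.mmej_max:
            raise ValueError("mmej_min must be <= mmej_max")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class RepairEvent:
    """Inferred signature of one repair junction (fields in bp unless noted)."""

    read_id: str
    left_match: int          # a: maximal read-prefix match vs left flank
    right_match: int         # b: maximal read-suffix match vs right flank
    del_5prime: int          # left-flank bases absent (left-greedy convention)
    del_3prime: int          # right-flank bases absent, incl. the MH span
    del_total: int           # reference bases absent from the read
    insertion_seq: str
    insertion_len: int
    mh_len: int              # apparent microhomology at the junction
    ambiguity: int           # breakpoint-placement ambiguity (= mh_len)
    is_mmej: bool
    event_class: str
    outside_window: bool = False
    ad_retained: bool = False


def parse_read_id(read_id: str) -> dict:
    """Split ``cohort|mouse|reaction|clone``; trailing fields are optional."""
    parts = read_id.split("|")
    keys = ("cohort", "mouse", "reaction", "clone")
    return {k: (parts[i] if i < len(parts) else None) for i, k in enumerate(keys)}


def _first_n(s: str, limit: int) -> int:
    i = s.find("N", 0, limit)
    return limit if i < 0 else i


def _lcp(a: str, b: str) -> int:
    """Length of the longest common prefix; ``N`` never matches."""
    n = min(len(a), len(b))
    lo, hi = 0, n
    while lo < hi:  # binary search for the first mismatch
        mid = (lo + hi + 1) // 2
        if a[:mid] == b[:mid]:
            lo = mid
        else:
            hi = mid - 1
    return min(lo, _first_n(a, lo), _first_n(b, lo))


def _lcs(a: str, b: str) -> int:
    """Length of the longest common suffix; ``N`` never matches."""
    n = min(len(a), len(b))
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if a[len(a) - mid :] == b[len(b) - mid :]:
            lo = mid
        else:
            hi = mid - 1
    k = lo
    for s in (a, b):
        i = s.rfind("N", len(s) - k)
        if i >= 0:
            k = min(k, len(s) - 1 - i)
    return k


def _lcp_mm(a: str, b: str, budget: int) -> int:
    """Greedy prefix extension tolerating up to ``budget`` substitutions."""
    n = min(len(a), len(b))
    i = used = 0
    while i < n:
        if a[i] == "N" or b[i] == "N":
            break
        if a[i] != b[i]:
            if used >= budget:
                break
            used += 1
        i += 1
    return i


def _lcs_mm(a: str, b: str, budget: int) -> int:
    n = min(len(a), len(b))
    i = used = 0
    while i < n:
        ca, cb = a[len(a) - 1 - i], b[len(b) - 1 - i]
        if ca == "N" or cb == "N":
            break
        if ca != cb:
            if used >= budget:
                break
            used += 1
        i += 1
    return i


def call_junction(
    read: JunctionRead, cutref: CutReference, params: CallParams = CallParams()
) -> RepairEvent:
    """Decompose one read into (deletions, insertion, microhomology).

    ``a`` is maximized first, then ``b``; an overlap of the two matches is the
    junction microhomology, a gap between them the insertion (mutually
    exclusive by construction).  Raises :class:`UnalignableReadError` when the
    read matches either flank at 0 bp.
    """
    left, right = cutref.left_flank, cutref.right_flank
    seq = read.sequence
    n = len(seq)
    if params.max_mismatch > 0:
        a = _lcp_mm(seq, left, params.max_mismatch)
        b = _lcs_mm(seq, right, params.max_mismatch)
    else:
        a = _lcp(seq, left)
        b = _lcs(seq, right)
    if a == 0 or b == 0:
        side = "left" if a == 0 else "right"
        raise UnalignableReadError(
            f"read {read.id!r} matches the {side} flank at 0 bp"
        )
    if a + b > n:
        mh = a + b - n
        insertion = ""
    else:
        mh = 0
        insertion = seq[a : n - b]
    del5 = len(left) - a
    del3 = len(right) - (b - mh)
    del_total = del5 + del3
    ins_len = len(insertion)
    if ins_len and del_total:
        event_class = "deletion+insertion"
    elif ins_len:
        event_class = "insertion"
    elif del_total:
        event_class = "deletion"
    else:
        event_class = "exact"
    outside = False
    if params.window is not None:
        outside = (
            del5 > params.window.max_del_5prime or del3 > params.window.max_del_3prime
        )
    return RepairEvent(
        read_id=read.id,
        left_match=a,
        right_match=b,
        del_5prime=del5,
        del_3prime=del3,
        del_total=del_total,
        insertion_seq=insertion,
        insertion_len=ins_len,
        mh_len=mh,
        ambiguity=mh,
        is_mmej=params.mmej_min <= mh <= params.mmej_max,
        event_class=event_class,
        outside_window=outside,
    )


def reconstruct_read(event: RepairEvent, cutref: CutReference) -> str:
    """Rebuild the read implied by an event; round-trip oracle for the caller.

    For every event produced by :func:`call_junction` with exact matching, the
    output equals the input read byte-for-byte.
    """
    if event.mh_len > 0 and event.insertion_len > 0:
        raise InconsistentEventError(
            "an event cannot carry both microhomology and an insertion"
        )
    if event.insertion_len != len(event.insertion_seq):
        raise InconsistentEventError("insertion_len does not match insertion_seq")
    b_eff = event.right_match - event.mh_len
    if b_eff < 0:
        raise InconsistentEventError("mh_len exceeds right_match")
    if event.left_match > len(cutref.left_flank) or event.right_match > len(
        cutref.right_flank
    ):
        raise InconsistentEventError("match lengths exceed flank lengths")
    right = cutref.right_flank
    return (
        cutref.left_flank[: event.left_match]
        + event.insertion_seq
        + (right[len(right) - b_eff :] if b_eff else "")
    )


def anchor_read(read: JunctionRead, construct: ReporterConstruct, cutref: CutReference) -> JunctionRead:
    """Map a primer-bounded amplicon onto flank coordinates.

    Rescued PCR products begin at the forward primer and end at the reverse
    complement of the reverse primer, while the caller anchors reads at flank
    position 1.  When a read starts/ends with the primers, the reference
    segments outside the primer sites -- which the assay cannot observe and
    assumes intact -- are attached so the read becomes flank-anchored.  Reads
    already starting at the flank start are returned unchanged.
    """
    from .construct import reverse_complement

    seq = read.sequence
    left, right = cutref.left_flank, cutref.right_flank
    fwd = construct.primer_fwd
    if seq.startswith(fwd) and not left.startswith(fwd):
        pos = left.find(fwd)
        if pos > 0:
            seq = left[:pos] + seq
    rc_rev = reverse_complement(construct.primer_rev)
    if seq.endswith(rc_rev) and not right.endswith(rc_rev):
        pos = right.rfind(rc_rev)
        if pos >= 0 and pos + len(rc_rev) < len(right):
            seq = seq + right[pos + len(rc_rev) :]
    if seq is read.sequence:
        return read
    return JunctionRead(id=read.id, sequence=seq, source_reaction=read.source_reaction)


def _ad_retained(seq: str, excised: str, k: int) -> bool:
    if len(excised) < k:
        return excised in seq
    return any(seq.find(excised[i : i + k]) >= 0 for i in range(0, len(excised) - k + 1, k))


def batch_analyze(
    reads: Iterable[JunctionRead],
    cutref: CutReference,
    params: CallParams = CallParams(),
    construct: Optional[ReporterConstruct] = None,
    dedupe: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Call every read; apply the one-unique-junction-per-reaction rule.

    With ``dedupe`` enabled, at most one event per (source_reaction, junction
    signature) pair is retained, emulating the rule that only one junction
    with a unique sequence from each PCR reaction enters the analysis.  Reads
    without a reaction id are never deduplicated against each other.  Returns
    ``(events, rejects, info)`` where ``info`` counts dropped duplicates and
    unalignable reads.
    """
    rows: list[dict] = []
    rejects: list[dict] = []
    seen: set = set()
    n_dup = 0
    excised = construct.excised_sequence if construct is not None else None
    for read in reads:
        if construct is not None:
            read = anchor_read(read, construct, cutref)
        reaction = read.source_reaction
        if reaction is None:
            parsed = parse_read_id(read.id)
            reaction = parsed["reaction"]
        try:
            event = call_junction(read, cutref, params)
        except UnalignableReadError as exc:
            rejects.append({"read_id": read.id, "reason": str(exc)})
            continue
        if params.detect_ad_retention and excised:
            event.ad_retained = _ad_retained(read.sequence, excised, params.ad_kmer)
        if dedupe and reaction is not None:
            key = (
                reaction,
                event.left_match,
                event.right_match,
                event.mh_len,
                event.insertion_seq,
            )
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
        row = asdict(event)
        row.update(parse_read_id(read.id))
        rows.append(row)
    events = pd.DataFrame(rows) if rows else pd.DataFrame(columns=_EVENT_COLUMNS)
    rejects_df = (
        pd.DataFrame(rejects) if rejects else pd.DataFrame(columns=["read_id", "reason"])
    )
    info = {
        "n_input": len(rows) + len(rejects) + n_dup,
        "n_events": len(rows),
        "n_duplicates_dropped": n_dup,
        "n_unalignable": len(rejects_df),
    }
    return events, rejects_df, info


_EVENT_COLUMNS = [
    "read_id", "left_match", "right_match", "del_5prime", "del_3prime",
    "del_total", "insertion_seq", "insertion_len", "mh_len", "ambiguity",
    "is_mmej", "event_class", "outside_window", "ad_retained",
    "cohort", "mouse", "reaction", "clone",
]
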