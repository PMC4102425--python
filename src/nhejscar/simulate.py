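"""Synthetic reporter constructs, repair events, reads, and FACS tables.

Every pipeline stage is testable without external data: this module builds
random reporter constructs with known geometry (optionally planting direct
repeats so a known MMEJ channel exists), simulates repair events through two
channels (canonical end joining with geometric end resection and optional
insertions; microhomology-mediated joining at repeat pairs), emits the
resulting junction reads with a ground-truth table, and draws flow-cytometry
counts for the efficiency readout.

Generator contracts that the caller's recovery guarantees rely on:

* deletion sizes are sampled truncated to the detection window, so every read
  is rescuable;
* insertion sequences are boundary-safe -- their first/last base never
  extends the flank matches -- so ``del_total`` and ``insertion_len`` are
  exactly recoverable from the read;
* chance microhomology at canonical-joining junctions is *not* suppressed:
  random flank sequence is allowed to create apparent MH, which is precisely
  what the random-joining null describes, so called ``mh_len`` may exceed the
  planted value by chance extension.

The default study design emulates the published assay scale: 30 junctions per
cohort (young/old) for each of five cell types, detection windows of 886 and
750 bp, a 16-bp repeat planted in the intron (its longest microhomology),
insertion-bearing fractions between a third and two thirds, and efficiency
fold-declines with age between 1.8 and 3.8 with the strongest drop in skin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .caller import JunctionRead
from .construct import (
    ConstructError,
    CutReference,
    CutSite,
    DetectionWindow,
    ReporterConstruct,
    derive_cut_reference,
    detection_window,
    reverse_complement,
)
from .null import junction_mh
from .stats import FacsCounts

I_SCEI_SITE = "TAGGGATAACAGGGTAAT"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class RepeatCollisionError(ConstructError):
    """Planted repeats overlap each other or a primer site."""


class GroundTruthMismatchError(ValueError):
    """Truth and called tables do not cover the same read ids."""


@dataclass(frozen=True)
class SimParams:
    """Per-cohort simulation parameters.

    Resection lengths are geometric on {0, 1, 2, ...} with the stated means
    (bp), truncated to the detection window; insertion lengths are geometric
    on {1, 2, ...}.  ``p_mmej`` is the probability a junction joins at a
    microhomology pair of >= ``mmej_min`` bp; ``p_insertion`` applies to the
    canonical-joining channel only.  ``seq_error_rate`` is the per-base
    substitution probability (0 for clean Sanger-clone consensus).
    """

    n_events: int = 60
    p_mmej: float = 0.2
    resection_mean_5p: float = 80.0
    resection_mean_3p: float = 80.0
    p_insertion: float = 0.5
    insertion_len_mean: float = 25.0
    seq_error_rate: float = 0.0
    mmej_min: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.p_mmej, self.p_insertion, self.seq_error_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (self.resection_mean_5p, self.resection_mean_3p, self.insertion_len_mean):
            if m <= 0:
                raise ValueError("means must be > 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_construct(
    seed: int = 0,
    intron_len_5p: int = 1000,
    intron_len_3p: int = 850,
    planted_repeats: Sequence[tuple[int, int, int]] = (),
    primer_offset_5p: int = 886,
    primer_offset_3p: int = 750,
    primer_len: int = 25,
    ad_len: int = 300,
    max_background_mh: Optional[int] = None,
    name: str = "synthetic-reporter",
) -> tuple[ReporterConstruct, CutReference]:
    """Build a random reporter construct with known geometry.

    ``planted_repeats`` is a list of ``(length, offset_left, offset_right)``:
    an identical random sequence is written at both offsets (bp from the
    respective cut edge to the repeat's cut-proximal end), creating a known
    MMEJ junction with that microhomology.  ``primer_offset_*`` set the
    detection window; defaults mirror the assay's 886/750 bp windows.
    ``max_background_mh`` regenerates the flanks (deterministically) until no
    chance microhomology within the window exceeds the cap *before* planting;
    useful for constructs whose longest MH must be the planted one.
    Deterministic in ``seed``.
    """
    if primer_offset_5p + primer_len > intron_len_5p:
        raise ConstructError("left flank too short for the forward primer placement")
    if primer_offset_3p + primer_len > intron_len_3p:
        raise ConstructError("right flank too short for the reverse primer placement")
    children = np.random.SeedSequence(seed).spawn(40)
    last_err: Optional[Exception] = None
    for child in children:
        rng = np.random.default_rng(child)
        try:
            return _build_construct_once(
                rng, intron_len_5p, intron_len_3p, planted_repeats,
                primer_offset_5p, primer_offset_3p, primer_len, ad_len,
                max_background_mh, name,
            )
        except ConstructError as err:
            last_err = err
            if isinstance(err, RepeatCollisionError):
                raise
    raise ConstructError(f"could not build a valid construct: {last_err}")


def _build_construct_once(
    rng, len5, len3, repeats, off5, off3, plen, ad_len, max_bg_mh, name
) -> tuple[ReporterConstruct, ReporterConstruct]:
    left = _random_dna(rng, len5)
    right = _random_dna(rng, len3)
    window = DetectionWindow(off5, off3)
    if max_bg_mh is not None:
        bg = CutReference(left, right, len(left))
        if _longest_window_mh(bg, window) > max_bg_mh:
            raise ConstructError("background microhomology exceeds cap")
    # plant repeats; track occupied intervals (copy + 1-bp margins) to detect
    # collisions.  The bases immediately flanking the two copies are forced to
    # mismatch between copies so the planted joint's microhomology is exactly
    # the repeat length, not a chance extension of it.
    occupied_left = [(len5 - off5 - plen, len5 - off5)]   # forward primer site
    occupied_right = [(off3, off3 + plen)]                # reverse primer site
    left_l, right_l = list(left), list(right)
    for length, o_left, o_right in repeats:
        if o_left + length >= len5 or o_right + length >= len3:
            raise RepeatCollisionError("planted repeat does not fit within the flanks")
        rep = _random_dna(rng, length)
        li = (len5 - o_left - length, len5 - o_left)
        ri = (o_right, o_right + length)
        for lo, hi in occupied_left:
            if li[0] - 1 < hi and lo < li[1] + 1:
                raise RepeatCollisionError("planted repeat collides on the left flank")
        for lo, hi in occupied_right:
            if ri[0] - 1 < hi and lo < ri[1] + 1:
                raise RepeatCollisionError("planted repeat collides on the right flank")
        occupied_left.append(li)
        occupied_right.append(ri)
        left_l[li[0] : li[1]] = rep
        right_l[ri[0] : ri[1]] = rep
        for (flank, idx), (other, odx) in (
            ((left_l, li[0] - 1), (right_l, ri[0] - 1)),
            ((left_l, li[1]), (right_l, ri[1])),
        ):
            if idx >= 0 and odx >= 0 and idx < len(flank) and odx < len(other):
                if flank[idx] == other[odx]:
                    choices = [b for b in "ACGT" if b != flank[idx]]
                    other[odx] = choices[int(rng.integers(3))]
    left, right = "".join(left_l), "".join(right_l)
    cutref_check = CutReference(left, right, len(left))
    if max_bg_mh is not None and repeats:
        # reject builds where chance sequence still beats the planted repeats
        if _longest_window_mh(cutref_check, window) != max(r[0] for r in repeats):
            raise ConstructError("chance microhomology exceeds the planted repeats")
    excised = I_SCEI_SITE + _random_dna(rng, ad_len) + reverse_complement(I_SCEI_SITE)
    sequence = left + excised + right
    primer_fwd = left[len5 - off5 - plen : len5 - off5]
    primer_rev = reverse_complement(right[off3 : off3 + plen])
    construct = ReporterConstruct(
        name=name,
        sequence=sequence,
        cut_sites=(
            CutSite(position=len5, overhang_length=4, orientation="forward"),
            CutSite(position=len5 + len(excised), overhang_length=4, orientation="reverse"),
        ),
        excised_interval=(len5 + 1, len5 + len(excised)),
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
    )
    return construct, derive_cut_reference(construct)


def _longest_window_mh(cutref: CutReference, window: DetectionWindow) -> int:
    ref = cutref.joined
    cut = cutref.cut_coordinate
    max5 = min(window.max_del_5prime, len(cutref.left_flank) - 1)
    max3 = min(window.max_del_3prime, len(cutref.right_flank) - 1)
    best = 0
    for i in range(cut - max5, cut + 1):
        for j in range(cut + 1, cut + 2 + max3):
            if i == cut and j == cut + 1:
                continue
            m = junction_mh(i, j, ref, cut)
            if m > best:
                best = m
    return best


def mmej_candidates(
    cutref: CutReference, window: DetectionWindow, min_mh: int = 5
) -> list[tuple[int, int, int]]:
    """All breakpoint pairs within the window whose junction MH >= min_mh.

    Returned as (i, j, mh) triples in joined-reference coordinates; these are
    the microhomology joints the MMEJ simulation channel can use.
    """
    ref = cutref.joined
    cut = cutref.cut_coordinate
    max5 = min(window.max_del_5prime, len(cutref.left_flank) - 1)
    max3 = min(window.max_del_3prime, len(cutref.right_flank) - 1)
    out = []
    for i in range(cut - max5, cut + 1):
        for j in range(cut + 1, cut + 2 + max3):
            if i == cut and j == cut + 1:
                continue
            m = junction_mh(i, j, ref, cut)
            if m >= min_mh:
                out.append((i, j, m))
    return out


def _truncated_geometric(rng, mean: float, upper: int) -> int:
    """Geometric on {0, 1, ...} with the given mean, resampled to <= upper."""
    p = 1.0 / (mean + 1.0)
    for _ in range(1000):
        d = int(rng.geometric(p)) - 1
        if d <= upper:
            return d
    return upper


def _boundary_safe_insertion(rng, length: int, left_next: str, right_prev: str) -> str:
    """Random insertion whose ends cannot extend the flank matches."""
    ins = list(_random_dna(rng, length))
    banned_first = {left_next} if left_next else set()
    banned_last = {right_prev} if right_prev else set()
    if length == 1:
        banned = banned_first | banned_last
        choices = [b for b in "ACGT" if b not in banned]
        ins[0] = choices[int(rng.integers(len(choices)))]
    else:
        if ins[0] in banned_first:
            choices = [b for b in "ACGT" if b not in banned_first]
            ins[0] = choices[int(rng.integers(len(choices)))]
        if ins[-1] in banned_last:
            choices = [b for b in "ACGT" if b not in banned_last]
            ins[-1] = choices[int(rng.integers(len(choices)))]
    return "".join(ins)


def simulate_events(
    cutref: CutReference,
    params: SimParams,
    window: DetectionWindow,
    seed: Optional[int] = None,
    cohort: str = "sim",
    candidates: Optional[list[tuple[int, int, int]]] = None,
    n_mice: int = 5,
) -> tuple[list[JunctionRead], pd.DataFrame, dict]:
    """Simulate repair events and emit reads plus a ground-truth table.

    Each event picks the MMEJ channel with probability ``p_mmej`` (joining at
    a sampled repeat pair, deleting the span between the copies) or the
    canonical channel (independent geometric 5'/3' resections, optional
    boundary-safe insertion).  Requested MMEJ with no available repeat within
    the window falls back to the canonical channel and is counted in the info
    dict.  Reads carry ids ``cohort|mouse|reaction|clone`` with one PCR
    reaction per clone, so deduplication never drops simulated events.
    """
    if seed is not None and params.seed is not None and seed != params.seed:
        raise ValueError("seed given both directly and in params")
    actual_seed = seed if seed is not None else params.seed
    rng = np.random.default_rng(actual_seed)
    left, right = cutref.left_flank, cutref.right_flank
    L, R = len(left), len(right)
    cut = cutref.cut_coordinate
    ref = cutref.joined
    if candidates is None:
        candidates = mmej_candidates(cutref, window, params.mmej_min)
    max5 = min(window.max_del_5prime, L - 1)
    max3 = min(window.max_del_3prime, R - 1)
    reads: list[JunctionRead] = []
    truth_rows: list[dict] = []
    n_mmej_fallback = 0
    for k in range(params.n_events):
        mouse = (k % n_mice) + 1
        read_id = f"{cohort}|m{mouse}|r{k + 1}|c1"
        use_mmej = rng.random() < params.p_mmej
        if use_mmej and not candidates:
            use_mmej = False
            n_mmej_fallback += 1
        if use_mmej:
            i, j, mh = candidates[int(rng.integers(len(candidates)))]
            d5, d3 = cut - i, j - cut - 1
            ins = ""
            channel = "MMEJ"
            seq = ref[:i] + ref[j - 1 :]
        else:
            d5 = _truncated_geometric(rng, params.resection_mean_5p, max5)
            d3 = _truncated_geometric(rng, params.resection_mean_3p, max3)
            ins = ""
            if rng.random() < params.p_insertion:
                ins_len = int(rng.geometric(1.0 / params.insertion_len_mean))
                left_next = left[L - d5] if d5 >= 1 else ""
                right_prev = right[d3 - 1] if d3 >= 1 else ""
                ins = _boundary_safe_insertion(rng, ins_len, left_next, right_prev)
            channel = "cNHEJ"
            mh = 0 if ins else junction_mh(cut - d5, cut + d3 + 1, ref, cut)
            seq = left[: L - d5] + ins + right[d3:]
        if params.seq_error_rate > 0.0:
            seq = _substitute_errors(rng, seq, params.seq_error_rate)
        reads.append(JunctionRead(id=read_id, sequence=seq, source_reaction=f"{cohort}|r{k + 1}"))
        truth_rows.append(
            {
                "read_id": read_id,
                "channel": channel,
                "del_5prime": d5,
                "del_3prime": d3,
                "del_total": d5 + d3,
                "insertion_seq": ins,
                "insertion_len": len(ins),
                "mh_len": mh if channel == "MMEJ" else 0,
                "chance_mh_len": mh,
            }
        )
    truth = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["read_id", "channel", "del_5prime", "del_3prime", "del_total",
                 "insertion_seq", "insertion_len", "mh_len", "chance_mh_len"]
    )
    info = {"n_events": len(reads), "n_mmej_fallback": n_mmej_fallback,
            "n_candidates": len(candidates)}
    return reads, truth, info


def _substitute_errors(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for idx in hits:
        choices = _BASES[_BASES != arr[idx]]
        arr[idx] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_facs(
    true_efficiency: float,
    n_total: int = 20_000,
    seed: Optional[int] = None,
    transfection_rate: float = 0.25,
    sample: str = "sim",
    rng: Optional[np.random.Generator] = None,
) -> FacsCounts:
    """Draw per-transfection FACS counts with a known true efficiency.

    ``n_dsred ~ Binomial(n_total, transfection_rate)`` and
    ``n_gfp ~ Binomial(n_dsred, true_efficiency)``, so the expected
    GFP+/DsRed+ ratio equals ``true_efficiency`` exactly.
    """
    if not (0.0 <= true_efficiency <= 1.0):
        raise ValueError("true_efficiency must lie in [0, 1] for binomial sampling")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_dsred = int(rng.binomial(n_total, transfection_rate))
    n_gfp = int(rng.binomial(n_dsred, true_efficiency)) if n_dsred else 0
    return FacsCounts(sample=sample, n_gfp=n_gfp, n_dsred=n_dsred, n_total=n_total)


def recovery_report(truth: pd.DataFrame, called: pd.DataFrame) -> dict:
    """Per-field exact-recovery rates of the caller against ground truth.

    Reports exact-recovery fractions for ``del_total`` and ``insertion_len``,
    the fraction with called ``mh_len`` exactly equal to and >= the planted
    value (chance extension can only increase it), and the channel-vs-MMEJ
    classification confusion counts.  Raises on read-id mismatch; two empty
    tables give an empty report.
    """
    if truth.empty and called.empty:
        return {"n": 0}
    t_ids, c_ids = set(truth["read_id"]), set(called["read_id"])
    if t_ids != c_ids:
        raise GroundTruthMismatchError(
            f"{len(t_ids - c_ids)} truth-only and {len(c_ids - t_ids)} called-only ids"
        )
    merged = truth.merge(called, on="read_id", suffixes=("_true", "_called"))
    n = len(merged)
    mmej_called = merged["is_mmej"].astype(bool)
    mmej_true = merged["channel"] == "MMEJ"
    return {
        "n": n,
        "del_total_exact": float((merged["del_total_true"] == merged["del_total_called"]).mean()),
        "insertion_len_exact": float(
            (merged["insertion_len_true"] == merged["insertion_len_called"]).mean()
        ),
        "mh_exact": float((merged["mh_len_called"] == merged["mh_len_true"]).mean()),
        "mh_ge_planted": float((merged["mh_len_called"] >= merged["mh_len_true"]).mean()),
        "channel_tp": int((mmej_true & mmej_called).sum()),
        "channel_fp": int((~mmej_true & mmej_called).sum()),
        "channel_fn": int((mmej_true & ~mmej_called).sum()),
        "channel_tn": int((~mmej_true & ~mmej_called).sum()),
    }


# ---------------------------------------------------------------------------
# Default study design: five cell types, two ages, known planted truths.
# Efficiencies, fold-declines, and channel fractions are fixed plausible
# values reproducing the assay's qualitative patterns (see docs/methods.md).
# ---------------------------------------------------------------------------

STUDY_TISSUES = ("astrocytes", "heart", "kidney", "lung", "skin")

STUDY_DESIGN: dict[str, dict] = {
    "astrocytes": dict(
        eff_young=0.18, fold=1.8,
        p_mmej=(0.20, 0.33), p_ins=(0.50, 0.50),
        resect=((80, 70), (90, 80)), ins_mean=(18, 30),
    ),
    "heart": dict(
        eff_young=0.22, fold=2.0,
        p_mmej=(0.17, 0.43), p_ins=(0.50, 0.45),
        resect=((100, 90), (60, 55)), ins_mean=(25, 15),
    ),
    "kidney": dict(
        eff_young=0.45, fold=2.4,
        p_mmej=(0.27, 0.13), p_ins=(0.63, 0.37),
        resect=((80, 70), (80, 70)), ins_mean=(25, 15),
    ),
    "lung": dict(
        eff_young=0.40, fold=2.8,
        p_mmej=(0.17, 0.40), p_ins=(0.67, 0.40),
        resect=((70, 60), (110, 95)), ins_mean=(25, 12),
    ),
    "skin": dict(
        eff_young=0.42, fold=3.8,
        p_mmej=(0.20, 0.20), p_ins=(0.50, 0.50),
        resect=((70, 65), (95, 85)), ins_mean=(20, 20),
    ),
}

# Planted direct repeats (length, offset_left, offset_right): one 16-bp
# repeat -- the longest microhomology of the emulated intron -- plus two
# short ones enriching the endogenous MMEJ joint pool.
STUDY_REPEATS: tuple[tuple[int, int, int], ...] = ((16, 300, 260), (7, 60, 45), (6, 120, 180))


@dataclass
class StudyData:
    """One simulated cohort study with full ground truth."""

    construct: ReporterConstruct
    cutref: CutReference
    window: DetectionWindow
    reads: dict[str, list[JunctionRead]]       # cohort label -> reads
    truth: dict[str, pd.DataFrame]             # cohort label -> truth table
    facs: pd.DataFrame                         # tissue, age, mouse, rep, counts
    params: dict[str, SimParams] = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    n_per_cohort: int = 30,
    n_mice: int = 5,
    n_transfections: int = 4,
    design: Optional[dict[str, dict]] = None,
    mouse_effect_sd: float = 0.15,
) -> StudyData:
    """Simulate the full cohort study with known ground truth.

    Five cell types x two ages, ``n_per_cohort`` junctions each (default 30
    young + 30 old = 60 per cell type), plus ``n_transfections`` FACS runs for
    each of ``n_mice`` mice per cohort.  Per-mouse efficiency carries a
    lognormal random effect (``mouse_effect_sd`` on the log scale).
    Deterministic in ``seed``.
    """
    design = STUDY_DESIGN if design is None else design
    construct, cutref = make_construct(seed=seed, planted_repeats=STUDY_REPEATS)
    window = detection_window(construct, cutref)
    candidates = mmej_candidates(cutref, window, min_mh=5)
    ss = np.random.SeedSequence(seed)
    # independent child streams: one per cohort for events, one for FACS
    cohort_list = [(t, age) for t in sorted(design) for age in ("young", "old")]
    children = ss.spawn(len(cohort_list) + 1)
    facs_rng = np.random.default_rng(children[-1])
    reads: dict[str, list[JunctionRead]] = {}
    truth: dict[str, pd.DataFrame] = {}
    params_used: dict[str, SimParams] = {}
    facs_rows: list[dict] = []
    for (tissue, age), child in zip(cohort_list, children[:-1]):
        cfg = design[tissue]
        a = 0 if age == "young" else 1
        params = SimParams(
            n_events=n_per_cohort,
            p_mmej=cfg["p_mmej"][a],
            resection_mean_5p=cfg["resect"][a][0],
            resection_mean_3p=cfg["resect"][a][1],
            p_insertion=cfg["p_ins"][a],
            insertion_len_mean=cfg["ins_mean"][a],
            seq_error_rate=0.0,
        )
        label = f"{tissue}_{age}"
        cohort_rng_seed = int(np.random.default_rng(child).integers(2**31 - 1))
        r, t, _ = simulate_events(
            cutref, params, window, seed=cohort_rng_seed, cohort=label,
            candidates=candidates, n_mice=n_mice,
        )
        reads[label], truth[label], params_used[label] = r, t, params
        eff = cfg["eff_young"] if age == "young" else cfg["eff_young"] / cfg["fold"]
        for mouse in range(1, n_mice + 1):
            mouse_eff = min(1.0, eff * float(np.exp(facs_rng.normal(0.0, mouse_effect_sd))))
            for rep in range(1, n_transfections + 1):
                counts = simulate_facs(
                    mouse_eff, sample=f"{label}|m{mouse}|t{rep}", rng=facs_rng
                )
                facs_rows.append(
                    {
                        "tissue": tissue, "age": age, "mouse": mouse, "rep": rep,
                        "sample": counts.sample, "n_total": counts.n_total,
                        "n_gfp": counts.n_gfp, "n_dsred": counts.n_dsred,
                    }
                )
    return StudyData(
        construct=construct,
        cutref=cutref,
        window=window,
        reads=reads,
        truth=truth,
        facs=pd.DataFrame(facs_rows),
        params=params_used,
    )
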