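# Methods

This note documents the models and conventions behind `nhejscar`, the
reasoning for parameter defaults, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing its
outputs.  Coordinates are 1-based closed intervals on the top strand
throughout the public API.

## The assay being modelled

A chromosomal GFP gene is split by a large intron containing a "killer" exon
flanked by two inverted I-SceI recognition sites.  Expressing I-SceI cuts
both sites (non-compatible 4-nt 3′ overhangs, so simple religation of the
excised piece is disfavoured); end joining of the two retained intron ends
restores GFP, read out by flow cytometry as the GFP⁺/DsRed⁺ ratio
(DsRed normalizes transfection efficiency).  Repair junctions are rescued by
PCR with intron-internal primers, cloned, Sanger-sequenced, and aligned back
to the construct.  The published design this package emulates used detection
windows of 886 bp (5′) and 750 bp (3′), 30 junctions per cohort for each of
five cell types from young and old animals (300 total), and 20,000 cells per
FACS acquisition.

## Construct model

A `ReporterConstruct` is a single FASTA record plus an annotation (cut
sites, the excised interval, the two rescue primers).  `derive_cut_reference`
removes the excised interval by slicing: the post-cut reference is
`left_flank + right_flank`, and slicing is exact
(`left + excised + right == sequence`, byte for byte).  Overhang bases are
not modelled structurally: junction reads are double-stranded clone
consensus, so the strandedness of the cut intermediate is unobservable, and
any retained overhang bases are simply part of whichever flank the
annotation's excised interval assigns them to (default: retained on the
flanks, i.e. distal to the killer exon).  Whether overhang bases count as
"deleted" therefore follows from the annotation, and the choice is visible
in the annotation file rather than hidden in code.

`detection_window` measures, on each flank, the distance from the primer's
cut-proximal end to the cut edge: a deletion larger than that removes the
primer site and the junction can never be amplified.  The window is
invariant to padding the construct outside the primer sites.  The reverse
primer is located as its reverse complement on the top strand (standard PCR
convention).  `N` is allowed in constructs but never matches during calling.

## Junction calling

Each read is decomposed against the flanks by two maximal exact anchored
matches: `a`, the longest read prefix matching a left-flank prefix, and `b`,
the longest read suffix matching a right-flank suffix (`N` terminates both).

* `a + b > len(read)`: the matches overlap; the overlap `mh = a + b − len`
  is the junction's apparent microhomology, and the breakpoint is ambiguous
  over exactly those `mh` bases (`ambiguity = mh`).
* `a + b < len(read)`: the gap `read[a+1 .. len−b]` is the insertion.
* `a + b = len(read)`: a blunt junction.

Microhomology and insertion are mutually exclusive by construction.  The
decomposition is canonicalized **left-greedily**: `a` is maximized first, so
microhomology bases are attributed to the left flank
(`del_5prime = len(left) − a`; the MH span counts toward `del_3prime`).
This attribution only shifts the per-side split; `del_total` — the number of
reference bases absent from the read, `(L − a) + (R − b) + mh` — and
`mh_len` are invariant to it, which is why the ambiguity is reported rather
than resolved.  `reconstruct_read` rebuilds
`left[1..a] + insertion + right[R−(b−mh)+1..R]` and equals the input read
exactly for every event the exact-mode caller produces; this round trip is
the pipeline's core self-check.

Junctions with ≥ 5 bp and ≤ 25 bp of microhomology are classified MMEJ
(`CallParams.mmej_min/mmej_max`): MMEJ characteristically anneals at 5–25 bp
repeats, while shorter apparent MH arises frequently by chance.  Deletions
are categorized as small (1–500 bp) or large (> 500 bp); a deletion of
exactly 500 bp is small.

Reads matching a flank at 0 bp on either side are rejected as unalignable
(recorded in a rejects table, never fatal in batch mode).  Deletions beyond
the detection window set an `outside_window` flag instead of rejecting,
since they indicate an annotation/primer inconsistency worth inspecting.
Batch analysis applies the uniqueness rule of the cloning protocol: at most
one event per (PCR reaction, junction signature), so identical clones from
one reaction are counted once while identical junctions arising in different
reactions — independent repair events — are both kept.  Reads without a
reaction id are never deduplicated.

Rescued amplicons begin at the forward primer rather than at the flank
start; `anchor_read` converts them to flank coordinates by attaching the
reference segments outside the primer sites, which the assay cannot observe
and assumes intact.  An optional mismatch-tolerant mode (greedy extension
through ≤ k substitutions) exists for noisy reads; it is off by default and
the reconstruction guarantee holds only in exact mode.  Optionally, reads
whose sequence contains k-mers of the excised interval are flagged
`ad_retained` (single-cut / uncut survivors of the enzymatic depletion step)
and excluded from cohort statistics.

## The random-joining null

If break ends are joined at uniformly random breakpoints, flank sequence
alone makes many junctions *look* microhomology-mediated.  The null
enumerates every breakpoint pair `(i, j)` with `i` within `max_del_5prime`
of the cut and `j` within `max_del_3prime` — including one-sided deletions,
excluding the single zero-deletion blunt pair (apparent MH is undefined
without a deleted span; both choices are switchable), giving
`n_pairs = (max5+1)(max3+1) − 1`.  Weighting is uniform (no resection-length
prior): that is what "joined at random" means.  By default the enumeration
is restricted to the primer-rescuable window, because only such junctions
are observable; a full-intron mode exists for comparison.

Two per-pair MH definitions are provided.  `apparent_mh(i, j)` is the
backward-anchored convention: the longest `k ≤ span` with
`ref[i−k+1..i] == ref[j−k..j−1]`.  The default `junction` mode is the
**caller-consistent** value: with `d5`, `d3` the per-side deletions and
`e_fwd`, `e_back` the forward/backward repeat extensions at the breakpoints,

```
mh(i, j) = min(e_fwd, d5) + min(e_back, d3)
```

which equals exactly the `mh_len` the caller reports for the read
`ref[1..i] + ref[j..end]` (derivable from the anchored-match definition of
`a` and `b`; verified pair-by-pair against the caller in the test suite).
Using the caller-consistent mode, the null and the observed calls measure
the same quantity, so a cohort simulated by uniform random joining
reproduces `p_mh_ge[1]` to binomial accuracy — the calibration the package
asserts.  For random base composition the two-sided junction MH gives
`P(MH ≥ 1) ≈ 1 − (3/4)² = 43.75 %`, which is why the published ~44 % chance
baseline emerges from sequence composition alone rather than from any tuned
constant.

`mh_excess_test` compares a cohort's observed `MH ≥ k` fraction to the null
probability as a one-proportion z test (the null is an exhaustive constant,
not an estimate).  The comparison is made over **insertion-free junctions**:
the null enumerates deletion junctions only, and a junction with an
insertion cannot display microhomology under the caller's contract, so
including inserted junctions would dilute the observed fraction with
structural zeros.

## Cohort statistics

Percentages of junctions with a feature are compared with the pooled
two-proportion z statistic
`(p1 − p2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2))`, two-sided normal p — the "two
sample t test between percents" of desk calculators.  Its empirical type-I
error at α = 0.05 is asserted to lie in [0.02, 0.08] under a simulated null
(p = 0.3, n = 30/30, 5,000 replicates).  Per-junction sizes are compared
with the classical pooled-variance unpaired t test.  Degenerate inputs are
flagged rather than erroring: pooled proportion 0 or 1 → statistic 0, p = 1;
zero pooled variance with equal means → p = 1, with unequal means → p = 0
plus a degeneracy flag.

`mean_del` and `mean_ins` average over feature-bearing junctions only
(junctions with no deletion say nothing about deletion size); an
`include_zeros` switch gives all-junction means, and summaries record which
convention produced them via the API call, not a hidden global.  Cohort
summaries are permutation-invariant and merge with count-weighting.  No
multiple-testing correction is applied by default (per-metric α = 0.05,
matching the assay's reporting convention); Benjamini–Hochberg is available.

NHEJ efficiency is `n_gfp / n_dsred` per transfection; replicate sets are
summarized as mean ± s.e.m., and the age effect as
`fold = mean(young) / mean(old)`.

## Synthetic-data generator

The generator exists so every stage has known ground truth.  Defaults
mirror the emulated study's scale and observations:

| parameter | default | rationale |
|---|---|---|
| junctions per cohort | 30 young + 30 old per cell type (60 per type, 300 total) | the published design |
| detection window | 886 / 750 bp | the published primer placement |
| resection length | geometric on {0,1,…}, means 60–110 bp per side by cohort, truncated to the window | single-parameter law; only the observed *range* (deletions 1–990 bp) is known, so the law is pluggable |
| insertion frequency | 0.37–0.67 by cohort | observed insertion-bearing fractions of 33–67 % |
| insertion length | geometric on {1,2,…}, means 12–30 bp | observed range 1–138 bp at n = 300 |
| MMEJ channel probability | 0.13–0.43 by cohort, rising with age in heart/lung | the observed qualitative age pattern |
| planted repeats | one 16-bp + 7-bp + 6-bp pair | the emulated intron's longest microhomology is 16 bp |
| FACS | 20,000 cells; DsRed⁺ ~ Bin(n, 0.25), GFP⁺ ~ Bin(DsRed⁺, efficiency) | expected ratio equals the true efficiency exactly |
| efficiency | young 0.18–0.45 by tissue; fold-decline 1.8–3.8, strongest in skin | the published pattern |
| mouse effect | lognormal, σ = 0.15 | visible inter-mouse spread without swamping the age effect |

Channels: an MMEJ event joins at a repeat pair sampled from the enumerated
candidates with junction MH ≥ 5 within the window (planted or endogenous),
deleting the spanned sequence; a c-NHEJ event draws independent 5′/3′
resections and, with the cohort's insertion probability, an insertion.  Two
generator contracts make exact recovery provable: deletions are sampled
truncated to the window (every read is rescuable), and insertion sequences
are *boundary-safe* — their terminal bases are resampled so they cannot
extend the flank matches — so `del_total` and `insertion_len` are exactly
recoverable from the read.  Chance microhomology at c-NHEJ junctions is
deliberately **not** suppressed: random flank sequence creating apparent MH
is precisely what the null describes, so called `mh_len` may exceed the
planted value (never fall below it), and the generator records both the
planted and the chance-inclusive value.

Planted repeats are written with mismatched 1-bp margins on both copies so
the planted joint's MH is exactly the repeat length; with
`max_background_mh` set, flank draws whose chance MH would exceed the
planted repeat are rejected deterministically, which is how "the longest MH
in this construct is the planted one" is made a provable fixture property.

Substitution errors (Sanger noise) are supported; indel errors are not —
clone consensus essentially never contains them, and they would break the
caller's exact-decomposition contract, which is a deliberate scope boundary.
The generator does not model PCR/cloning bias, Ku/DNA-PK kinetics,
cell-cycle dependence, or translocations; passing tests demonstrate that the
*analysis* is correct for reads of the assumed structure, not that real
junction spectra follow geometric resection laws.

## Validation problem sizes

The test suite validates, among others: round-trip reconstruction and exact
del/insertion recovery on 10⁴ error-free simulated junctions; caller
equivalence with an independently coded exhaustive decomposition oracle
(complete enumeration over short flanks plus 10³ random larger cases);
`apparent_mh` against a naive k-loop oracle for all pairs on references up
to 50 nt; null normalization, the all-A homopolymer closed form, and
agreement of a 10⁴-junction simulated random-joining cohort with
`p_mh_ge[1]` within 3 binomial standard deviations; percent-test size over
5,000 null replicates; and planted-parameter recovery over 500 seeded
replicates — MMEJ fractions (0.15 vs 0.40) per 60-junction cohort with
Wilson 95 % intervals, and the planted deletion mean on the pooled
300-junction estimate (the study's total) with a t interval, both requiring
≥ 93 % empirical coverage.  The deletion-mean truth is the truncated-
geometric closed form computed from the law, independent of the sampler.

## Known limitations

* Insertions are reported verbatim; their templated origin is not traced.
* The per-side deletion split is a convention (left-greedy); only
  `del_total`, `mh_len` and the ambiguity are attribution-free.
* The mismatch-tolerant mode is greedy and approximate; quantitative
  guarantees hold for exact mode only.
* The null's uniform pair weighting is the definition of "random joining",
  not a mechanistic resection model; a resection-biased null would need a
  length prior the assay cannot identify.
* With `N` bases, matches terminate conservatively; heavily masked reads
  will be called with inflated deletions or rejected.
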