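# nhejscar

Repair-junction scar analysis for two-cut GFP end-joining reporter assays.

Double-strand breaks (DSBs) are repaired in vertebrates mostly by
non-homologous end joining (NHEJ).  A widely used way to measure NHEJ in
cells is a chromosomal GFP reporter whose coding sequence is split by a large
intron carrying a "killer" exon between two inverted I-SceI sites: cutting
both sites excises the killer exon, and end joining of the two intron ends
restores a functional GFP.  Sequencing the repaired junctions reveals the
*scar* each event left behind — deletions from end resection, templated or
untemplated insertions, and short direct repeats (microhomologies) at the
joint that mark microhomology-mediated end joining (MMEJ), the mutagenic
alternative pathway.

`nhejscar` implements the complete analysis behind such an assay:

* **Construct model** — the annotated reporter (cut sites, excised interval,
  rescue primers), the post-cut reference flanks, and the primer-bounded
  *detection window*: the largest deletion on each side of the break that the
  rescue PCR can still amplify.
* **Junction caller** — decomposes each Sanger-sequenced junction read as
  `read = left_flank[1..a] + insertion + right_flank[R−b+mh+1..R]`, reporting
  per-side deletions, total deleted bases, insertion sequence, apparent
  microhomology `mh` (with its breakpoint ambiguity) and the MMEJ class
  (junction MH of 5–25 bp).  Exact string matching, left-greedy
  canonicalization, guaranteed read reconstruction.
* **Random-joining null** — exhaustively enumerates every rescuable
  breakpoint pair `(i, j)` in the window and tabulates the microhomology each
  junction would *appear* to have if ends were joined at random; for random
  base composition `P(MH ≥ 1) = 1 − (3/4)² ≈ 44 %`.  Observed cohorts are
  tested against this baseline with a one-proportion z test.
* **Cohort statistics** — per-cohort junction spectra (mean deletion size,
  % deletions > 500 bp, insertion frequency and size, % MH, % MMEJ), the
  pooled two-proportion z test ("t test between percents"), the classical
  unpaired t test, and NHEJ efficiency as the GFP⁺/DsRed⁺ FACS ratio with
  young/old fold-changes.
* **Synthetic data** — a fully seeded generator of constructs (with planted
  repeats creating known MMEJ joints), repair events through c-NHEJ and MMEJ
  channels, junction reads with per-read ground truth, and binomial FACS
  counts — so the whole pipeline is testable without any external data.

## Worked example

```python
from nhejscar import CutReference, JunctionRead, call_junction

cutref = CutReference(left_flank="ACGTCAT", right_flank="CATGGA", cut_coordinate=7)
ev = call_junction(JunctionRead(id="j1", sequence="ACGTCATGGA"), cutref)
print(ev.del_total, ev.mh_len, ev.insertion_seq)   # -> 3 3 ''
```

The flanks share the 3-mer `CAT`, so the seamless-looking read `ACGTCATGGA`
is a 3-bp deletion junction whose breakpoint is ambiguous over 3 bp of
apparent microhomology.  Running the full simulated five-tissue study
(`python examples/05_full_study.py`) prints:

```
junctions called: 300 (window 886/750 bp)

NHEJ efficiency fold-decline with age (GFP+/DsRed+ ratios):
  astrocytes  2.20x
  heart       1.87x
  kidney      2.21x
  lung        2.75x
  skin        3.64x

microhomology use vs random joining (insertion-free junctions, n=187):
  observed 67.9% vs expected 43.7% (z = 6.68, p = 2.4e-11)

MMEJ junctions (5 bp <= MH): young 18.7% vs old 33.3%
```

i.e. end-joining efficiency declines 1.9–3.6-fold with age (strongest in
skin), junctions use microhomology far more often than random joining would
produce, and the MMEJ share rises with age — each number recomputed from the
simulated reads, with per-read ground truth available for validation.

The other scripts in `examples/` each demonstrate one capability
(construct/window, junction calling, the null distribution, cohort
comparison).  A thin CLI wraps the same functions:

```bash
nhejscar simulate --out demo --seed 2 --single-cohort
nhejscar analyze --construct demo/construct.fasta --config demo/construct.yaml \
                 --reads demo/reads.fasta --out demo_out
nhejscar null --construct demo/construct.fasta --config demo/construct.yaml
```

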