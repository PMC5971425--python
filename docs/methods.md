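# Methods

## Data model and conventions

All intervals are BED-style 0-based half-open; peaks are unstranded.
A `PeakSet` is a coordinate-sorted collection of intervals for one
assay/cell/replicate; merging coalesces overlapping *and abutting*
intervals (the union of covered bases is conserved). "Overlap" between
two peaks means ≥ 1 shared base unless a rule states otherwise; the
overlap of one interval against a peak set is measured against the
*merged coverage* of that set, so split target peaks are not counted
twice. Unsorted BED input is sorted with a logged warning rather than
rejected; malformed coordinates fail with the offending line number.
Interval arithmetic is implemented on per-chromosome numpy arrays with
prefix sums and binary search (O((n+m) log m)); the test suite checks
it against brute-force boolean-mask oracles on toy chromosomes and
against `bedtools` as an external reference.

## Consensus rules

Three rules reflect common practice for the three assay designs:

* **Accessibility (2 biological replicates):** pool and merge all
  replicate peaks; keep a merged region iff *both* replicates
  contribute ≥ 1 overlapping peak. Output coordinates are the merged
  region footprint, not a per-replicate intersection — the retained
  unit is the reproducible region.
* **Histone ChIP (4 replicates):** same rule with "all replicates"
  required; `at_least_two` is also available.
* **Methylation ensemble (≥ 2 peak callers):** a merged region is kept
  iff some pair of peaks from two distinct callers inside it overlaps
  by ≥ 100 bp. The rule is enforced on the best supporting pair; with
  more than two callers any qualifying pair suffices.

Consensus never covers a base not covered by at least one replicate,
and is invariant to replicate order.

## AREs and establishment

An **active regulatory element** is an H3K27ac consensus peak that
overlaps accessible chromatin in the same cell type. The element keeps
its H3K27ac footprint (filtering, not clipping): acetylation peaks are
the biological unit, and stable footprints keep nearest-TSS distances
stable. The retained fraction is reported (empirically ≳ 95% in this
kind of data) and is NaN-flagged with a warning when the H3K27ac set
is empty.

Specificity between two mature cell types is a reciprocal-overlap
partition: an ARE is *cell-specific* when it overlaps nothing in the
other cell's ARE set; reciprocally overlapping AREs are merged into
*shared* clusters counted once. The partition is symmetric.

The **establishment stage** of an ARE is the earliest stage, in an
ordered list from most primitive to the ARE's own cell type, whose
accessibility profile overlaps it by ≥ 1 bp. An ARE absent from all
earlier stages is "established de novo" at its first present stage.
Because real differentiation data show cumulative presence, the
per-stage presence fractions (not only the earliest-stage histogram)
are reported; under nested accessibility these fractions are
non-decreasing along the lineage.

Chromatin state against progenitor reference marks is the 2×2 overlap
table: active (both), poised (H3K4me1 only), open (neither), plus an
explicit fourth class, *acetylated_only* (H3K27ac without H3K4me1),
which three-state schemes leave undefined; the four fractions always
sum to 1.

Nearest-TSS assignment minimizes the edge distance (0 if the TSS lies
inside the element) over all TSS on the element's chromosome; exact
ties are broken by the lexicographically smallest gene id so results
are deterministic. Elements on chromosomes without any TSS are
explicitly unassigned and excluded (but counted) in target-expression
summaries. The promoter/enhancer boundary is 1 kb, inclusive: distance
≤ 1000 bp → cPE, otherwise cEE.

## Expression and methylation accounting

"Expressed" means TPM ≥ 1 (boundary inclusive; threshold exposed).
Maintenance chains are cumulative intersections of expressed sets along
a lineage, hence non-increasing. Percentages are rounded **half-up**
(integer precision for chain tables, one decimal for methylation
tables), matching how such tables are conventionally printed.
The two-proportion test is the pooled-variance z-test (via statsmodels),
two-sided, with p clipped to [0, 1]; identical observed proportions
short-circuit to (z = 0, p = 1) even when the pooled variance is
degenerate. The suite cross-checks it against a seeded Monte-Carlo
binomial null under the mid-p convention.

Methylation overlap is reported per specificity class and establishment
stage: among AREs established at stage *s*, the fraction overlapping
≥ 1 stage-*s* methylation consensus peak.

## Permutation test

The null model re-places each query interval independently and
uniformly on its chromosome of origin with width preserved
(start ~ U[0, L − width]); randomized intervals may overlap each other,
and no masked/gap regions are modeled. The statistic is the number of
query intervals overlapping the target set. Reported are the null mean
and sample standard deviation, z = (obs − mean)/sd (NaN-flagged when
sd = 0), and the one-sided empirical p with the (k+1)/(n+1)
correction, whose floor at 500 iterations is 1/501 ≈ 0.002. The default
alternative is "greater" (enrichment); "less" exists for depletion.
Same seed ⇒ bit-identical results. Calibration is tested: querying
truly random sets yields approximately uniform p-values, and the null
mean for a single interval matches the closed-form hit probability
(w_target + w − 1)/(L − w + 1).

By default the *first* (query) set is randomized; which set a published
analysis randomized is usually unstated, and the choice only matters
when the two sets have very different width distributions.

## Synthetic cohort

The generator plants a complete ground truth and emits plain-text
inputs (chrom.sizes, BED, TSV) plus a ready-to-run pipeline config.

**Geometry.** The genome (default 19 × 10 Mb) is partitioned into
equal gene blocks, one TSS per block center; an ARE occupies at most
one slot on each side of a TSS, with distances sampled away from the
1 kb promoter boundary (≤ 950 bp or ≥ 1051 bp) so the ±25 bp replicate
jitter cannot flip the proximity class, and margins sized so jittered
features never cross block or slot boundaries. This deterministic
block design — rather than free placement with rejection retries — is
what makes the nearest-gene, specificity and establishment labels
*exactly* recoverable: no unrelated TSS can sit closer than the
intended target and no two planted features can collide. A density
check still rejects configurations whose requested peak bases exceed
~50% of the genome or whose blocks are too narrow for the distance
geometry.

**Planted structure.** Establishment stages, chromatin states,
proximity classes and per-stage methylation flags are assigned by
largest-remainder quota, so aggregate fractions equal the configured
proportions exactly; randomness only shuffles which element gets which
label. Accessibility is nested by default (established ⇒ present at
all later stages of the lineage); a non-nested mode drops accessibility
stage-to-stage with a persistence probability to stress the
earliest-stage rule. Replicates are jittered copies (±25 bp per edge)
plus replicate-specific noise peaks placed in ARE-free blocks, which
the consensus rules must remove; methylation is emitted as two
peak-caller tracks whose jitter (±20 bp) provably preserves the 100 bp
ensemble rule. A configurable 3% of H3K27ac peaks are planted without
accessibility to realize the ~97% ARE retention fraction.

**Defaults as study conditions.** Class sizes 2098 / 6386 / 5989
(erythroid-specific / megakaryocytic-specific / shared); establishment
fractions (0.64, 0.20, 0.14, 0.02) for the erythroid-like class,
(0.89, 0.08, 0.01, 0.02) for the megakaryocyte-like class and
(0.98, 0.01, 0.005, 0.005) shared; state proportions
(0.20, 0.57, 0.21, 0.02), (0.46, 0.41, 0.09, 0.04), (0.79, 0.15, 0.04,
0.02); per-stage methylation overlap rates (0.186, 0.037, 0.115,
0.021) and (0.078, 0.023, 0.178, 0.124); target-expression rates 0.82 /
0.89 / 0.93. Expression is an on/off Markov structure: 65.33% of
20,000 genes on at the root (~13.1k expressed), stage retention 0.900
(CMP), 0.745/0.940 (erythroid branch), 0.949/0.943 (megakaryocytic
branch), de novo gain 0.06 per stage; expressed TPM = 1 + LogNormal(1,
1.5), silent TPM ~ U(0, 1). Peak widths are N(500, 100²) truncated to
[200, 800] bp. These choices reproduce the qualitative asymmetry the
pipeline is built to detect: an erythroid program assembled largely at
commitment versus a megakaryocytic program inherited from the root.

**What the generator does not emulate:** signal strength and peak
shape, sequence content and motifs, mappability gaps, correlated
replicate failure modes, distance-dependent enhancer–gene wiring
beyond nearest-TSS, or biological coupling between chromatin state and
establishment stage (planted independently per class). Passing the
recovery tests therefore demonstrates correctness of the interval
logic and accounting on data with known truth — not robustness to
every artifact of real sequencing data.

## Problem sizes and runtime

The default cohort (≈ 14.5k AREs, 20k genes, 190 Mb genome) generates
in ~2 s and runs through the full pipeline, including 12 permutation
tests of 500 iterations each, in ~10 s on one CPU. The test suite uses
a reduced cohort (940 AREs, 2,000 genes, 24 Mb) for end-to-end checks,
a 6,000-ARE cohort for parameter-recovery acceptance, 200 × 500
iterations for null calibration, and ≤ 100 kb chromosomes for the
brute-force oracle comparisons.

## Known limitations

* Establishment inference assumes reasonably nested accessibility; with
  strong stage-to-stage loss the earliest-overlap rule can date an
  element earlier than its continuous history (the non-nested generator
  mode exists to probe this).
* Shared AREs are dated and methylation-flagged along the first
  lineage's stage naming; for stages after the branch point a shared
  element is planted (and detected) in both branches.
* The pooled z-test is a large-sample approximation; for very small
  counts an exact or simulated test is preferable (the Monte-Carlo
  cross-check quantifies the gap).
* The permutation null does not model masked genome regions or
  chromosome-length biases beyond preserving chromosome of origin.
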