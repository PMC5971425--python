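# commitpoint

Tools for timing **lineage commitment** along ordered hematopoietic
differentiation paths from interval-based regulatory genomics data:
chromatin accessibility (ATAC-seq peaks), histone marks (H3K27ac,
H3K4me1), DNA methylation (MBD-seq peaks) and expression (TPM tables).

The guiding question is when a mature cell type's regulatory program is
*established*: do committed erythroid cells and megakaryocytes inherit
their open chromatin and active enhancers from multipotent progenitors
(LSK → CMP → committed progenitor → mature cell), or do they build them
de novo at commitment? `commitpoint` answers this with a reusable,
fully tested pipeline, plus a synthetic-cohort generator with planted
ground truth so every stage can be validated end to end without any
external data.

## What it computes

* **Consensus peaks.** Replicate consensus on merged pooled regions —
  a region is kept when the required number of replicates ("all", or
  "at least two") each contribute a peak — and a peak-caller ensemble
  rule for methylation (≥ 2 tools, ≥ 100 bp pairwise overlap).
* **Active regulatory elements (AREs).** H3K27ac consensus peaks
  retained iff they overlap accessible (ATAC) chromatin by ≥ 1 bp,
  keeping the H3K27ac footprint. AREs of two mature cell types are
  partitioned into cell-specific and shared sets by reciprocal overlap.
* **Establishment stage.** For each ARE, the most primitive stage whose
  ATAC profile already contains it; AREs absent from every earlier
  stage are "established de novo". Per-stage presence fractions are
  cumulative along the lineage.
* **Chromatin state.** Against progenitor reference marks:
  *active* (H3K4me1 + H3K27ac), *poised* (H3K4me1 only), *open*
  (neither), *acetylated_only* (H3K27ac only).
* **Nearest TSS and proximity class.** Edge distance to the closest TSS
  genome-wide; candidate promoter element (cPE) within 1 kb (inclusive),
  candidate enhancer element (cEE) beyond.
* **Expression structure.** Expressed = TPM ≥ 1; maintenance chains
  (cumulative intersections of expressed sets along a lineage),
  three-set Venn accounting, pooled two-proportion z-tests.
* **Methylation overlap.** Fraction of AREs established at stage *s*
  overlapping stage-*s* methylation peaks.
* **Significance.** A from-scratch region-randomization permutation
  test: each query interval is re-placed uniformly on its own
  chromosome (width preserved), the overlap count is recomputed per
  iteration, and the one-sided empirical p-value uses the
  (k+1)/(n+1) correction — with 500 iterations the p-value floor is
  1/501 ≈ 0.002.

## Worked example

Generate a reduced synthetic cohort (two lineages, 940 planted AREs,
2,000 genes) and run the full pipeline:

```bash
commitpoint simulate --seed 11 --small --out cohort
commitpoint run cohort/pipeline.yaml
```

The report lands in `cohort/report/`. The establishment table
(`establishment.tsv`) recovers the planted establishment fractions of
the erythroid-like cell-specific AREs exactly:

```
class       stage   n_established  presence_fraction
a_specific  LSK     141            0.6409
a_specific  CMP     44             0.8409
a_specific  CFU-E   31             0.9818
a_specific  ERY     4              1.0
```

i.e. 64% of these AREs are already accessible in the multipotent root,
84% by the shared progenitor, and a late wave is established de novo at
commitment — while the megakaryocyte-like class starts at 89% in the
root. The maintenance chains (`maintenance_chains.tsv`) show the same
asymmetry at the transcriptome level:

```
lineage         stage   n_maintained  pct_of_root  pct_of_previous
erythroid       LSK     1311          100.0        100.0
erythroid       ERY     805           61.0         94.0
megakaryocytic  iMK     1054          80.0         95.0
```

and every ARE-vs-ATAC permutation test sits at the 500-iteration floor
(`p_empirical = 0.001996`, z ≈ 48–312), confirming that planted overlap
structure is far beyond chance placement. Per-ARE annotations
(establishment stage, chromatin state, nearest gene, cPE/cEE class,
methylation and expression flags) are written to
`are_catalog_<class>.tsv`.

The same steps are available as library calls
(`commitpoint.generate_cohort`, `commitpoint.run_pipeline`) and as
finer-grained subcommands (`consensus`, `mbd-consensus`, `permtest`).

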