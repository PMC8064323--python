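# h3k4pipe

Differential **H3K4me3 ChIP-seq island analysis** for two-group brain-tissue
study designs, together with a planted-truth synthetic data generator.

## The problem

Postmortem human brain specimens often have RNA too degraded for
transcriptome profiling, but promoter-associated histone modifications —
above all H3K4me3 — remain detectable in isolated chromatin for days after
death. A practical surrogate analysis therefore works at the level of
*enriched genomic intervals* ("islands") rather than transcripts: call
islands per sample, normalize libraries, merge islands across samples into
regions, annotate them against gene models, and compare per-gene promoter
and gene-body tag densities between groups (e.g. two clinical groups at
n = 3 each).

Because studies of this kind rarely deposit raw sequencing data, the
package ships a first-class synthetic generator that emulates the data
layer — genome, gene models, per-sample extended-fragment tags with
promoter-concentrated enrichment, genome sequence with planted motif
occurrences, and ChIP-qPCR Ct tables — each with a machine-readable truth
record, so every downstream statistic can be validated against what was
planted.

## The model

* **Island calling** (SICER-style): fragment midpoints are counted in
  windows (default 200 bp); a window with count *k* is *eligible* when the
  Poisson upper tail P(X ≥ k; λ) < 0.2 with background rate
  λ = N·w / G (N tags, window w, genome length G). Eligible windows
  separated by ≤ 600 bp chain into an island; island significance is the
  Poisson tail of its total count against λ scaled to the island length,
  Benjamini–Hochberg corrected across islands, kept at FDR < 1e-10.
* **Normalization**: every library is randomly downsampled, without
  replacement, to the tag count of the smallest sample.
* **Merged regions**: transitive closure of interval overlap across all
  samples — each region spans from the most upstream member start to the
  most downstream member end; a single-sample island defines its own
  region. Regions carry per-sample presence and group-level Venn counts.
* **Annotation**: region midpoints are classified strand-aware against the
  nearest gene into proximal/distal promoter (0–1 / 1–3 kb upstream),
  5′UTR / exon / intron / 3′UTR, proximal/distal downstream, or distal
  intergenic; genes are associated with peaks within 10 kb of their span.
* **Differential activity**: per-gene tag density (tags/kb, length
  corrected) in the promoter (TSS ± 1 kb) or gene body (TSS→TES); group
  means on the density scale; ratio (mean_B + c)/(mean_A + c) with
  pseudocount c = 0.5 tags/kb; two-sided Welch t-test on log₂ densities;
  the filter keeps |fold| ≥ 1.5 and p < 0.05.
* **Profiles**: tag-count matrices around gene bodies (±2 kb, meta-gene
  scaled), merged regions (±5 kb) and promoters (±1.5 kb) in 32-bp bins,
  k-means clustered into 5 groups; cross-group scatter QC reports Pearson
  r and the OLS slope of per-region group means.
* **Motif scanning**: JASPAR-format PFMs become log-odds weights with one
  background-distributed pseudocount; interval sequences ± 200 bp flanks
  are scanned on both strands with a min-max normalized score cutoff, and
  motifs are ranked by average sites per interval.
* **ChIP-qPCR**: percent input 100·2^((Ct_input − log₂(1/f)) − Ct_IP),
  fold over a matched gene-desert negative control, one-way ANOVA across
  postmortem timepoints with Bonferroni post-hoc, and the OLS decay slope
  of log₂ enrichment per hour.

## Worked example

```python
from h3k4pipe import PipelineConfig, run_pipeline, evaluate_against_truth

run_pipeline(PipelineConfig(seed=1), "run")   # full synthetic study
print(evaluate_against_truth("run"))
```

```
{'differential_sensitivity': 1.0, 'differential_null_pass_rate': 0.011764705882352941,
 'n_planted': 30, 'n_null': 170, 'spotlight_gene': 'g052',
 'spotlight_planted_fold': 2.3, 'spotlight_recovered_fold': 2.15541}
```

All 30 genes planted with a 3-fold between-group promoter change pass the
1.5-fold + p < 0.05 filter (sensitivity 1.0); only ~1% of unchanged genes
pass (the expected false-positive tail of the p < 0.05 term at n = 3); and
the single gene planted with a modest 2.3-fold promoter increase is
recovered at 2.16. The run directory also holds, per sample, island BED/TSV
and bedGraph tracks, the merged-region presence matrix and Venn counts,
feature-category pie fractions with a matched random-peak control, profile
matrices with cluster labels, the motif frequency table, qPCR statistics,
and a `manifest.json` with row counts and SHA-256 checksums — two runs with
the same seed produce identical manifests.

The same study runs from the shell:

```bash
h3k4pipe run-all --seed 1 --outdir run
```

with stage-level subcommands (`simulate`, `bin`, `callpeaks`, `downsample`,
`merge`, `annotate`, `diff`, `profile`, `motifscan`, `qpcr`) for re-running
pieces from intermediate files.

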