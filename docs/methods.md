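# Methods

This note documents the models implemented in `h3k4pipe`, the choices made
where the design was genuinely open, and what the synthetic study does and
does not establish about real data.

## Synthetic study design

The generator emulates a two-group (A vs B, n = 3 per group) H3K4me3
ChIP-seq comparison on a small fully mappable genome. Defaults:

| parameter | default | meaning |
|---|---|---|
| genome | 2 chromosomes × 2.5 Mb | synthetic assembly, uniform random sequence |
| genes | 200, spans 2–10 kb | uniformly placed, both strands, non-overlapping spans, 1–5 exons |
| depth | 100,000 tags/sample | Poisson library size; 0.02 tags/bp background density |
| fragment length | uniform 150–250 bp | in-silico 3′ extension range of sequenced tags |
| enriched genes | 120 | promoter-concentrated enrichment |
| base promoter fold | 8, spread ×/÷2 | per-gene fold drawn log-uniformly from [4, 16] |
| differential genes | 15 up + 15 down at 3-fold | the planted between-group effect |
| spotlight gene | 1 at 2.3-fold | one modest planted increase, recovered by the differential table |
| weak tier | 40 genes at fold 2.4 | borderline enrichment at the caller's detection limit |
| enrichment shape | Gaussian, σ = 500 bp, centre −250 bp from TSS | see below |
| qPCR | 6 timepoints 0–96 h, 3 replicates | exponential decay per antibody |

The genome and depth are scaled down from sequencing-study magnitudes
(tens of millions of unique alignments on a 3 Gb assembly) while
preserving the background density of the calibration experiments
(0.02 tags/bp, i.e. 200,000 tags per 10 Mb); all rate-based statistics
(Poisson tails, densities, folds) depend on density, not absolute size.

**Enrichment parametrization.** A gene's enrichment factor *f* for a group
is defined as the expected mean tag density over its TSS ± 1 kb promoter
window relative to the sample's genomic background. The Gaussian component
for the gene receives expected extra tags `(f − 1) · bg · 2000 / capture`,
where `capture` is the Gaussian mass falling inside the window. This makes
planted folds exactly the promoter-density folds the differential module
estimates, so recovery tests have closed-form expectations.

**Enrichment centre.** The Gaussian is centred 250 bp upstream of the TSS
(strand-aware, configurable). A mark centred exactly on the TSS makes the
midpoint of a symmetric island a coin flip between "proximal promoter" and
"5′UTR" under midpoint classification; centring on the core promoter
reproduces the promoter-dominant feature distribution expected of this
mark while keeping essentially all enrichment inside the ±1 kb window.

**Weak tier.** 40 genes are planted at fold 2.4, measured (by simulation)
to sit at the island caller's detection cliff at the default depth, so
per-sample presence fluctuates. This is what produces group-exclusive
merged regions in the Venn analysis, as marginal peaks do in real data.

**Seeding.** A single global seed fans out to per-sample substreams via a
CRC-32 hash of the sample label (`substream(seed, label)`), so outputs do
not depend on generation order and all seeds stay below 2³¹.

What the generator does **not** emulate: mappability gaps and blacklists,
GC and fragment-length bias, duplicate reads, chromatin input structure
(input is modelled only through the optional control-coverage hook of the
island caller), biological covariance between neighbouring genes, and
realistic annotation geometry (UTRs are a fixed 10% convention, see
below). Passing tests therefore demonstrate correctness of the statistics
under a clean Poisson-mixture world, not robustness to these artefacts.

## Island calling

Fragments are assigned to bins by midpoint (unambiguous single
assignment); the 32-bp binning is used for density tracks (bedGraph),
while scoring uses its own window grid (default 200 bp). The background
rate is global, λ = N·w/G with G the full genome length (synthetic genomes
are fully mappable; no masking). Eligibility is permissive
(P(X ≥ k; λ) < 0.2); stringency comes entirely from the island-level FDR.
Eligible windows chain when separated by ≤ gap (600 bp); the island count
includes tags in the intervening gap windows and is tested against λ
scaled by the spanned window count. Multiple testing uses Benjamini–
Hochberg q-values across the islands of one sample; islands with
q < 1e-10 are kept. The FDR is a BH q-value; an E-value-style score would
be an alternative reading of "FDR" in this family of callers — BH was
chosen and is documented here. When an input (control) coverage is given,
the expected count of an island is the maximum of the global background
and the depth-scaled input count over its span.

Degenerate inputs: zero total tags return an empty island list; a
zero-length genome is an error; window is rounded up to a multiple of the
bin size and gap to a multiple of the window, with a log message.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
on 20 pure-Poisson 10 Mb genomes at 200,000 tags the caller returns zero
islands; with 50 promoters planted at 10-fold it recovers ≥ 95% of them.

## Interval algebra

Coordinates are 0-based half-open throughout; book-ended intervals do not
overlap. Downsampling is without replacement to the smallest library and
is applied *before* island calling (normalization precedes interval
determination); the smallest sample is returned unchanged, making the
operation idempotent on already-normalized inputs. Merged regions are the
transitive closure of ≥ 1 bp overlap across samples, built by a sweep over
start-sorted islands; merging is idempotent. Group presence in the Venn
uses "any sample of the group contributes" — region-level pooling; a
stricter per-sample analysis is available through the presence matrix.

## Annotation

Classification is by region midpoint (regions can span several features;
pie charts need a single label); the full overlap information is
recoverable from the gene-association map. In-gene precedence is
5′UTR > 3′UTR > exon > intron, since UTRs are subsets of exons and
specific should beat general. Synthetic gene models have no real UTR
annotation, so by convention the first and last 10% of the gene span are
5′ and 3′UTR (configurable). Ties between candidate genes go to the
smallest |TSS distance|, then lexicographic gene id. Midpoints beyond the
1–3 kb windows are distal intergenic; the 10 kb margin is the
gene-association search radius (`genes_near_peaks`), not a pie category.
Random control peaks preserve the length multiset and are placed uniformly
over the genome (position chosen uniformly among all valid starts).

## Differential activity

Signal is raw_count / (window length in kb), counted by fragment
midpoint. Group means are taken on the density scale (the ratio describes
"group average signal values", not a log-scale mean). The pseudocount of
0.5 tags/kb (half a tag per kb, the usual half-count convention) guards
zero densities in both the ratio and the log transform. The test is a
two-sided Welch t-test on log₂(density + pseudocount) — robust to unequal
group variances at n = 3; a pooled-variance t is a config option. No
multiple-testing correction enters the pass filter (the screen is a raw
p < 0.05 fold-change filter); a BH column is emitted for transparency.
With one sample in a group the p-value is undefined and the filter falls
back to fold change only, with a logged warning. Records are sorted by p,
then |log₂ fold|.

## Profiles and clustering

Heatmap rows need fixed width, so gene bodies are rescaled to a 2,000
pseudo-bp meta-length before ±2 kb flanks; merged regions are anchored at
their midpoint (±5 kb) and promoters at the TSS (±1.5 kb), all in 32-bp
bins, oriented with upstream on the left (minus-strand rows are reversed
wholesale, which makes the strand-flip mirror exact). Flanks are snapped
up to the bin grid. Clustering is k-means (k = 5, 10 restarts, fixed
seed) on rows normalized to unit sum — a documented stand-in for the
unnamed "default" clustering of vendor heatmap tools; labels are
renumbered by descending mean raw signal so C1 is always the strongest
cluster and label assignment is reproducible. The scatter QC is Pearson r
plus the OLS slope (with intercept) of group-B on group-A per-region mean
densities.

Under the default study conditions the synthetic scatter r is ~0.3:
30 of ~90 called regions carry planted 3-fold anticorrelated differences,
a far larger differential fraction than a real cohort would show (it is
set high to estimate sensitivity with useful precision). The QC statistic
is reported as computed; reproducing any particular published r/slope
would require that study's data and is out of scope.

## Motif scanning

PFM → PWM uses one pseudocount mass distributed by the background:
`lo[b][i] = log2((n[b][i] + bg[b]) / (colsum[i] + 1)) − log2(bg[b])`.
Scores are min-max normalized per motif, so 1.0 is the consensus and the
default cutoff 0.85 is scale-free; proprietary matrix-similarity scores
with core regions and per-position information weights are a different
(unavailable) scheme, so published site counts from such tools are
qualitative references only. Windows containing N are skipped rather than
scored against background (avoids cutoff-dependent N artefacts);
overlapping hits are all reported; both strands are scanned (the
reverse-complement weight matrix is the row- and column-reversed forward
matrix). The headline statistic is total sites / interval count over
flank-extended (±200 bp, clipped) interval sequences. The bundled PFM
library (`SYN001`–`SYN003`) is synthetic, built for planted-truth tests,
and is not a measured binding profile.

## ChIP-qPCR statistics

Percent input includes the dilution adjustment log₂(1/input_fraction) on
the input Ct. Fold over negative divides by the matched (antibody,
timepoint, replicate) gene-desert control, making the control's own fold
exactly 1. Stability is a one-way fixed-effects ANOVA across timepoints
on fold-over-negative, with all pairwise pooled-variance t-tests and
Bonferroni adjustment (p × number of pairs, capped at 1); groups with
fewer than 2 replicates are an error. The decay slope is the OLS slope of
log₂ fold on hours (halving every 24 h gives −1/24 per hour exactly),
reported with its standard error.

## Pipeline and reproducibility

`run_pipeline` executes simulate → downsample → callpeaks → merge →
annotate → differential → profiles → motifscan → qpcr, writing plain-text
formats only (FASTA, BED6/BED12, bedGraph, TSV, JSON) and a manifest with
row counts and SHA-256 checksums of every output plus the full config.
Outputs contain no timestamps or absolute paths, so equal seeds give
byte-identical manifests. Optional PNG rendering of average plots is off
by default and never part of the checksummed artefact set.

Problem sizes in the shipped tests and acceptance script (20 × 10 Mb null
genomes, 10 Mb / 200,000-tag sensitivity and recovery runs, 20-seed
differential replicates, 100-seed qPCR power) were chosen to make the
binomial/sampling error of each estimated rate small relative to its
acceptance margin.

## Known limitations

- The Poisson background has no overdispersion; real ChIP-seq input shows
  local biases that would widen island-call error rates.
- Welch's t at n = 3 is low-powered for folds near the 1.5 cutoff; the
  planted-recovery guarantees hold for ≥ 3-fold effects.
- The annotation feature geometry (UTR convention, exon structure) is a
  synthetic convention, so category *fractions* are not comparable to a
  real genome's annotation proportions — only the classification logic is.
- Motif-site averages depend on the normalized-score cutoff; with
  information-poor matrices the 0.85 default admits substantial background
  hit rates (use a higher cutoff for planted-truth recovery).
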