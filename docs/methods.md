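# Methods

## The measurement problem

Between-sample normalization of RNA-seq counts is only defined up to a
per-sample constant, and the standard way of fixing that constant — make the
"typical" gene look unchanged — silently assumes that most genes do not
change. A perturbation of a global regulator violates the assumption: if
every gene is repressed 2.6-fold, median-based normalization will rescale the
repression away and report a quiet transcriptome. The spike-in design breaks
the circularity: a fixed mass of RNA from a second organism (10 parts per 90
parts target RNA in the emulated protocol) is added to every sample before
library preparation, so the spike-in genes form a reference subset whose true
abundance is constant across samples by construction.

`ttseqkit` implements both normalizations side by side because their
*disagreement* is the scientific signal: internal-mode factors absorb global
shifts, spike-in-mode factors preserve them.

## Size factors

Median-of-ratios: for reference gene i with counts K_i1..K_im, the
pseudo-reference is the geometric mean g_i across samples; the factor of
sample j is the median over i of K_ij / g_i. Conventions:

* genes with a zero in any sample are dropped from the reference (their
  geometric mean is degenerate);
* an even number of reference ratios is resolved by the arithmetic mean of
  the two central ratios (the ordinary sample median);
* name-based exclusions (suffixes `rRNA`, `RDN` by default, plus arbitrary
  id lists) apply to reference selection only — excluded genes are still
  normalized and reported downstream;
* factors are anchored to the cross-sample geometric mean, so they are
  meaningful up to a common constant: scaling one sample's counts by c
  multiplies its factor *relative to any other sample's* by exactly c, while
  the absolute factors move by c^((m−1)/m) and c^(−1/m). Contrasts between
  samples, which is what the downstream analyses consume, are unaffected by
  this anchoring.

The global transcription ratio (target reads / spike-in reads per sample,
condition-level replicate median) needs no size factors at all; it is the
most direct absolute readout and is reported alongside them.

## Differential test

Production differential-expression analyses of this kind of data typically
use a full NB-GLM framework with multi-factor designs; `ttseqkit`
deliberately ships a much simpler two-group test, because the quantity of
interest here is the interaction between *normalization mode* and
fold-change thresholds, not GLM machinery.

Per gene, on normalized counts: group means m₁, m₂ and the pseudocounted
effect `lfc = log2((m₁+1)/(m₂+1))`. The Wald statistic is lfc / SE(lfc) with
the delta-method SE from the NB variance function V(μ) = μ + αμ²:

    SE² = [V(m₁)/(n₁ m₁²) + V(m₂)/(n₂ m₂²)] / ln²2

(pseudocounted means in the denominators), two-sided p from the normal
reference. Genes with all-zero counts across both groups get an undefined p
and are excluded from multiple testing.

**Dispersion.** The per-gene method-of-moments estimate
α̂_i = max(0, (v̂_i − m̂_i)/m̂_i²), with v̂_i the within-group pooled sample
variance and m̂_i the mean of the two group means, has only n₁+n₂−2 degrees
of freedom; plugged directly into a normal-reference Wald test at n = 3 per
group it produces a t₄-like statistic and a null rejection rate of ~12% at
α = 0.05. `nb_test` therefore uses a single **common dispersion** — the mean
of the per-gene moment estimates across all expressed genes — which borrows
thousands of degrees of freedom while remaining a pure moments estimator (no
shrinkage prior, no trend fitting). Measured on null simulations (2,000
genes, 3 vs 3, ten seeds) the rejection rate at α = 0.05 is ≈ 0.05; on
simulations with 10% true genes at |log2FC| = 2, BH at 0.05 plus a twofold
call threshold gives sensitivity ≈ 1.0 at empirical FDR ≈ 0.01 (both
recomputed by the test suite on every run). The cost of a common α is
miscalibration for genes whose true dispersion is far from the genome
average; a caller with strong prior knowledge can pass `dispersion=`
explicitly. This test does not attempt to reproduce GLM-based p-values.

BH adjustment is the statsmodels step-up implementation behind a thin
validating wrapper (NaN propagation for untested genes). DE calls require
both FDR ≤ threshold and 2^|lfc| ≥ fold threshold; up/down sets are disjoint
by construction. Gene-set overlaps use the exact hypergeometric upper tail
P(X ≥ k) (one-sided enrichment) with a 0.5 continuity correction on the odds
ratio when a table cell is zero.

## Proximity association

Distances are interval-to-interval gaps (0 on ≥1 bp overlap),
strand-agnostic and intra-chromosomal; genes on chromosomes without any
feature are excluded from both partitions symmetrically and counted in the
result. The statistic is median(sig)/median(null). When either median is
zero — feature sets so dense that most genes overlap one — the ratio is
replaced by (zero-fraction of null) / (zero-fraction of significant):
per-partition *fractions* rather than raw tallies so unequal partition sizes
do not distort the value, and inverted relative to the median ratio so that
< 1 always reads "significant genes closer". The `fallback_used` flag is
always reported so consumers can tell the regimes apart. No permutation
p-value is attached to the ratio; the null behaviour (random significant
sets give median ratios within [0.8, 1.25] on the default synthetic genome)
is verified in the test suite instead.

Anchoring distances at gene bodies (not TSSs) is a choice: the feature sets
are unstranded and the emulated analysis names the transcript as the anchor.

## Read counting

Gene counting follows the reverse-stranded single-end convention: a read is
assigned to a gene when it overlaps by ≥ 1 bp and its strand is *opposite*
the gene's; a read overlapping g genes increments all g of them when
multi-overlap is enabled (otherwise ambiguous reads are discarded). Inputs
must be uniquely mapped — the standard upstream filter keeps primary,
uniquely mapped locations with fewer than three mismatches (`max_mismatches=2`).

For repeats, filtering keeps all candidate locations; an optional
`keep_best` mode restricts each read to locations tied at its minimum
mismatch count ("best possible locations"). The expanded table has one row
per (read, location) with weight exactly 1/k, so Σ weights = number of reads
(mass conservation, property-tested on random instances). A location
overlapping two repeat intervals contributes its full weight to each,
mirroring the multi-overlap gene rule; per-million normalization defaults to
the number of distinct filtered reads, each counted once regardless of k.

## Metagene matrices

The 200-column grid is 50 upstream bins (10 bp each), 100 body bins, 50
downstream bins. Gene bodies are rescaled by exact fractional-interval
averaging: bin boundaries are placed at real-valued positions start + jL/100
and the mean coverage over each sub-interval is computed from the coverage
cumulative sum with proportional weighting of partial bases. This is
deterministic, exactly constant-preserving (uniform coverage c gives every
bin c), strand-equivariant (a minus-strand gene on mirrored coverage gives
the identical row), and well defined for genes shorter than one bin per base.
Positions beyond chromosome ends contribute zero coverage over the full bin
width (missing-data-as-zero). Coverage tracks intended for metagene input
should first be divided by the spike-in size factor (`scale_coverage`), so
profiles are comparable across samples on the absolute scale.

Heat-map rendering and row clustering are out of scope; the matrix and the
mean/median profile are the exported artifacts.

## TES base bias

For each gene the sense-strand base at TES+o is read for offsets
o ∈ [−100, 100), with minus-strand genes read on the reverse complement and
positive offsets always pointing downstream. Offsets falling off a
chromosome end are removed from numerator and denominator at that offset.
Smoothing is a moving average over a 16-offset window; an even window has no
centre, and the fixed convention is offsets −8..+7 (documented because it is
observable: an affine input comes back shifted by half a step, whereas odd
windows reproduce it exactly). Edges are truncated and renormalized rather
than padded.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Defaults: 2,000 target genes and 500 spike-in genes (spike-in genes live on
dedicated chromosomes, mirroring a two-genome mapping setup), three
replicates per condition, gene lengths log-uniform on [500, 5000] bp
(straddling the 1,000 bp metagene body), intergenic gaps uniform on
[200, 2000] bp, 200 feature sites of 200 bp, 10% true-DE genes at
|log2FC| = 2 with random sign, 80% of them placed within 2 kb of a feature
site, NB dispersion 0.05, per-sample depth lognormal with σ = 0.1, and a
spike-in mass share of 10% (the 90:10 mixing ratio of the emulated
protocol). Counts are NB(μ, α) with
μ = base · 2^lfc·[treated, DE] · scale_condition·[target] · depth_sample;
spike-in gene means never receive the differential effect or the global
scale. Base expressions are lognormal around a 200-count mean, and the
spike-in bases are rescaled so the expected spike share is exact at unit
global scale — under a global repression the spike share rises, which is
precisely the effect the spike-in design measures.

What the generator does *not* emulate: sequencing error and mapping
ambiguity outside repeat families, GC/length biases, batch structure,
mean-dependent dispersion trends, correlated genes, or the TES-proximal
coverage peak caused by labelling bias (the A-rich window downstream of the
TES is simulated; its effect on read recovery is not). Passing tests
demonstrate correctness of the computations under this idealised model, not
robustness to every artefact of real libraries.

Each generator operation draws from its own child stream of the config seed
(`default_rng([seed, stream_id])`), so outputs are reproducible individually
and jointly.

## Validation set-up and problem sizes

The test suite cross-checks each core operation against an independent
brute-force oracle written with explicit loops: all-pairs nearest distances
(700 × 300 intervals), explicit geometric-mean/median size factors (50 × 6),
1/k accumulation over every (read, location, feature) triple (200 reads),
literal sub-bin integration for the metagene grid (gene lengths 37, 500,
1,000 and 4,999 on both strands, agreement to 1e-9), exhaustive
hypergeometric enumeration for the overlap test (universes up to 20), and the
literal BH step-up. Statistical properties use 2,000-gene simulations with
3 vs 3 replicates (ten seeds for null calibration, five for power/FDR) and
200 resampled gene sets for the proximity null — sizes chosen to keep the
whole suite under a minute while leaving Monte-Carlo error well inside the
asserted bands.

## Pipeline

`run_pipeline` chains simulate → sequence → reads → filter/count →
normalize → test → overlap → proximity → metagene → TES bias, writes one
TSV per result plus a bedGraph coverage track, and emits a manifest
(parameter echo, package version, SHA-256 of every output) sufficient to
re-run without the original command line. Stage timings go to `log.txt`
only, so identical configurations produce byte-identical result files; any
stage failure propagates with the stage name. The demo pipeline's overlap
stage uses the synthetic annotation size as the Fisher universe (the 6,049
default of `overlap_fisher` refers to the real yeast catalogue).
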