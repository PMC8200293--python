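# ttseqkit

Analysis toolkit for spike-in calibrated nascent-RNA sequencing (TT-seq) in a
two-organism design: a target transcriptome (e.g. *Saccharomyces cerevisiae*)
measured against a constant-mass spike-in transcriptome (e.g.
*Schizosaccharomyces pombe*). The package is aimed at experiments that
perturb a global regulator — such as degron-mediated condensin depletion —
where genome-wide shifts in transcriptional output are exactly the signal
that ordinary between-sample normalization erases.

## What it computes

**Size factors in two reference modes.** Median-of-ratios size factors
`s_j = median_i( K_ij / (∏_v K_iv)^(1/m) )` over a reference gene subset:
*internal* (target genes only; any global shift is absorbed into the factors,
so only relative, gene-specific changes remain) or *spike-in* (spike-in genes
only; because the spike-in mass is constant per sample, genome-wide shifts in
target transcription survive normalization). Genes with a zero count in any
sample are excluded from the reference, as are configurable name patterns
(defaults: names ending in `rRNA` or `RDN`).

**Global transcription ratio.** Per sample, total target-organism reads
divided by total spike-in reads, summarised per condition by the replicate
median — a direct readout of absolute transcriptional output.

**Differential expression.** Pseudocounted log2 fold changes
`log2((mean_t + 1)/(mean_c + 1))` on normalized counts, a two-group
negative-binomial Wald test with a common method-of-moments dispersion,
Benjamini–Hochberg FDR, and threshold calls (defaults FDR ≤ 0.05 and
fold change ≥ 1.5 or ≥ 2). Gene-set overlaps are tested with a one-sided
Fisher exact test on a configurable universe (default 6,049 genes, the
*S. cerevisiae* catalogue).

**Proximity association.** For each gene, the distance to its nearest
feature (condensin-binding sites, cohesin sites, ...; 0 if overlapping).
The statistic is `median(distance | significant) / median(distance | rest)`;
values below 1 mean differentially expressed genes cluster near the feature
set. If either median is zero the ratio falls back to the quotient of
zero-distance fractions (null over significant), preserving the orientation,
and the result is flagged.

**Multi-mapping repeat quantification.** Reads mapping to k locations (Ty
retrotransposon copies, for instance) are expanded to one row per location
with weight 1/k, so each read contributes exactly one unit of mass; weighted
counts over repeat intervals are reported raw and per million mapped reads.

**Metagene matrices.** Scale-regions coverage matrices (500 bp flanks, gene
body rescaled to 1,000 bp, 10 bp bins → 200 columns) computed by exact
fractional-interval averaging, plus column-wise mean/median profiles.

**TES base-composition bias.** The per-offset adenine fraction on the sense
strand in a ±100 bp window around transcription end sites, smoothed over a
sliding 16 bp window — the sequence bias relevant to 4-thiouracil-based
nascent-RNA enrichment.

**Synthetic data with ground truth.** A generator for two-organism gene
catalogues, feature sites spatially linked to true-DE genes,
negative-binomial counts with condition-level global scaling and a 10%
spike-in mass share, multi-mapping repeat reads, and genome sequence with an
optional A-rich window downstream of each TES. Every analysis above can be
exercised against known truth.

## Worked example

An end-to-end run on a synthetic dataset (2,000 target genes, 500 spike-in
genes, three replicates per condition, 10% true DE at |log2FC| = 2, 80% of
DE genes within 2 kb of a feature site):

```bash
ttseqkit run --out demo --seed 1
# run complete: demo
# median target/spike-in ratio [control]: 8.936
# median target/spike-in ratio [treated]: 9.683
```

The run directory contains, among others, `de_results.tsv`,
`proximity.tsv`, `overlap.tsv`, `metagene_profile.tsv` and `tes_bias.tsv`.
With this seed the DE stage calls 113 genes up and 95 down (208 calls, of
which 200 are truly differential — `overlap.tsv` reports the Fisher test of
the calls against the truth: overlap 200/208, p ≈ 1e-267 on the 2,000-gene
universe), and the proximity stage reports

```
feature_set_name  median_sig  median_null  ratio     fallback_used
sites             1236        11110        0.111251  False
```

i.e. called genes sit an order of magnitude closer to the feature sites than
unchanged genes — the expected signature, since the generator placed 80% of
true-DE genes near sites.

Re-running with a genome-wide repression
(`ttseqkit run --out demo2 --seed 1 --treated-scale 0.3846`) prints

```
median target/spike-in ratio [control]: 9.088
median target/spike-in ratio [treated]: 3.800
```

a control/treated quotient of ≈ 2.4 from the imposed 2.6-fold global scale
(slightly offset here because the simulated up-regulated genes add more mass
than the down-regulated genes remove). In internal normalization mode this
shift is invisible by construction; the spike-in mode and the global ratio
are what expose it.

Every subcommand (`simulate`, `filter`, `count-genes`, `count-repeats`,
`normalize`, `de`, `overlap`, `proximity`, `metagene`, `tes-bias`, `run`)
is a thin wrapper over the library; see `ttseqkit --help`.

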