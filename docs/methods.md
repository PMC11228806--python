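# Methods

This note describes the models and procedures implemented in `geomxeco`,
the choices made where a convention had to be pinned, and what the
synthetic validation does and does not demonstrate.

## Preprocessing model

GeoMx DSP counts arrive per probe; several probes may target one gene and a
pool of negative-control probes measures background.

**Probe collapse.** A gene's value in a segment is the arithmetic mean of
its probe counts after outlier removal. The outlier rule — drop a probe
whose count lies outside [0.1×, 10×] the median of the gene's probes in
that segment, applied only when the gene has ≥ 3 probes — is a deliberately
simple robust filter: with two probes there is no meaningful center to trim
against, and classical outlier tests (e.g. Grubbs) have no power at these
probe counts. When the rule would remove every probe, the plain mean is
used. Note the rule also removes zero counts whenever the probe median is
positive; for low-expression genes this biases the collapsed value slightly
upward, which is acceptable because such genes sit below the LOQ anyway.

**Limit of quantification.** LOQ per segment = geometric mean of the
negative probes plus `n_sd` (default 2) standard deviations. "Standard
deviation" of negative counts is read additively (arithmetic sample sd,
ddof = 1); a multiplicative variant (geomean × gsd^n_sd) is available via
`mode="geometric"` because the additive/multiplicative reading is genuinely
ambiguous in the field. Zero counts are replaced by a pseudo-count of 1
before the log so the geometric mean is defined; nonzero counts are left
untouched.

**Segment QC.** Default thresholds: sequencing saturation ≥ 0.8, nuclei
≥ 20, ≥ 5% of genes above LOQ. All are configurable; a segment must meet
every enabled threshold, and the report records each failure reason.

**Q3 normalization.** Per segment, Q3 is the 75th percentile of the genes
above that segment's LOQ (detected genes only — undetected genes say
nothing about scale). Each segment is multiplied by
geomean(all Q3s) / its Q3, so after scaling every segment's Q3 equals the
common geometric mean (asserted exactly in the tests). The log step is
log2(x + 1). Matrices carry an explicit state (`raw → q3 → log2q3`) and the
transforms refuse out-of-order application rather than double-normalizing.

## Clustering and signatures

Tumor segments are clustered on the log2-Q3 matrix restricted to the top-n
variance genes (default 500 of 1,000 synthetic genes; variance ties broken
by gene name). k-means uses Euclidean distance, k-means++ initialization,
50 iterations and the best of 200 attempts; the elbow search uses 10
attempts per k (1..10) since it only needs the WSS curve's shape, and picks
k* as the arg-max of the second forward difference of WSS — a reproducible
automation of the visual elbow. A flat zero-WSS curve yields k = 1 by
convention. Cluster labels are renumbered by ascending cluster-mean NE
score, so cluster 1 is always the least and cluster 3 the most
neuroendocrine regardless of k-means label permutation.

Signatures come from PCA loadings: the contribution of gene g to component
c is ℓ²gc normalized by the component's total squared loading; a gene is a
contributor when its larger contribution (PC1 vs PC2) exceeds the uniform
expectation 1/|universe| — the threshold a featureless dataset would give
every gene. Contributors are assigned to their dominant axis (which makes
the three lists disjoint by construction) and split by loading sign:
positive PC1 → cluster-1 signature, positive PC2 → cluster-2, negative
PC2 → cluster-3.

PCA signs are arbitrary, so two orientation conventions are provided.
`run_pca` flips each component so its largest-|loading| gene is positive
(deterministic and self-contained, but effectively a coin flip when two
gene programs of similar amplitude sit at opposite ends of a component).
`orient_pca_by_score` flips PC1/PC2 so their segment scores anticorrelate
with the NE score, pinning the intended semantics — non-NE at positive PC1,
NE at negative PC2 — whenever an NE score is available. The pipeline uses
the score-based orientation.

Cluster markers: per gene and cluster, a two-sided Wilcoxon rank-sum test
(cluster vs rest; exact null distribution at small n without ties,
normal approximation otherwise) plus a fold change computed as
log2(median Q3 in cluster / median Q3 in rest) on linear-scale values. A
marker needs p < 0.05 and linear fold change > 2 in either direction
(|log2FC| > 1); the >2× filter is applied on the linear scale. A zero
denominator median triggers a pseudo-count of 1 on both medians and a flag.

## Scoring

**ssGSEA.** Per sample, genes are ranked by expression descending (ties
broken by gene name, which makes scores identical across platforms). With
rank values N..1 and in-set weights |rank value|^α (α = 0.25), the
enrichment score is the sum over the list of the difference between the
weighted in-set cumulative frequency and the uniform out-of-set cumulative
frequency. Optional normalization divides the whole matrix by its global
max − min. Because the statistic is rank-based it is invariant to any
monotone per-sample transformation (asserted by test), which is also why
purity-model scores transfer between differently normalized matrices.

**NE score.** (ρ_NE − ρ_nonNE)/2, where ρ is the Pearson correlation of a
segment's signature-gene expression with an NE or non-NE reference profile.
The reference profiles are data inputs; the synthetic module derives them
from the planted program means. The score is antisymmetric under profile
swap and lives in [−1, 1].

**Purity model.** Ordinary least squares purity ~ intercept + stromal +
immune, refused when the design is ill-conditioned (condition number
> 1e8); predictions are clamped to [0, 1] with a flag. The synthetic
training table is generated in `pseudobulk` mode: bulk-like mixtures with
known purity are scored by un-normalized ssGSEA on the stromal and immune
sets — the same featurization later applied to segments — so the fitted
coefficients transfer. A `linear` mode emits an exact
purity = 1 − 0.8·stromal − 0.8·immune (+ noise) relation for
exact-recovery testing.

**Preranked GSEA.** Weighted Kolmogorov-Smirnov ES (weights |metric|,
exponent 1), null by redrawing same-size gene sets from the ranked
universe, NES = ES / mean |null ES| of the matching sign, p from the
same-sign null tail with add-one smoothing, BH correction across sets.
The ranking metric from a marker table is −log10(p)·sign(log2FC) with
p = 0 floored at 1e-300 and flagged.

## Deconvolution

The default solver runs active-set NNLS (Lawson–Hanson, via scipy) and
renormalizes the weights onto the simplex. This is scale-invariant — the
constraint absorbs any positive scaling of the segment — and exact on
noiseless mixtures. The `qp` mode solves the literal equality-constrained
problem by augmenting the design with a heavily weighted (1e6 × mean
reference value) sum-to-one row. Deconvolution runs on linear-scale Q3
values because mixtures are additive in linear space; log-scale input is
refused. The ν-SVR formulation used by web-based tools is intentionally out
of scope: the linear mixture model is the recoverable, testable core.

## Communication

Expression is min-max rescaled per gene to [0, 10] across all segments in
the run, so pair scores are bounded and comparable across pairs. Ligand
(receptor) activity is the geometric mean of subunit values in the sender
(receiver) segment; the pair score is √(ligand × receptor). A missing
subunit gene yields a missing score, not zero — absence of measurement is
not absence of signal. Population summaries take the maximum pair score
over the pairs mapped to a (sender population, receiver population); the
mean-of-min aggregator (mean over pairs of min(ligand, receptor) activity)
is the cross-check and is dominated by the max summary since
min(a,b) ≤ √(ab). Differential interactions between ecosystem groups use
two-sided Wilcoxon rank-sum across regions with BH correction; constant
scores give p = 1.

## Survival

Stratification uses the type-7 (linear-interpolation) empirical quantile,
default 0.75, with ties at the cutoff assigned to the low group — the
convention must be pinned for group sizes to be reproducible. Kaplan-Meier
estimation, the two-group log-rank test (1 df) and the Cox model come from
lifelines; Cox uses Efron tie handling and reports HR with a Wald 95% CI.
A group with zero events still yields curves but flags the test unstable;
the Cox fit requires ≥ 10 events. The univariable high-vs-low model is the
headline; covariates enter as declared numeric columns.

## Synthetic-data generator

The generator emulates the statistical structure of a ~10-patient DSP
cohort: 40 regions (32 paired tumor+TME, 4 tumor-only, 4 normal) allocated
across patients within a 3–6 regions/patient range; probe-level
negative-binomial counts (variance μ + μ²/φ, φ = 10 by default; φ → ∞
gives Poisson) with 3 probes/gene over 1,000 genes and 50 negative probes
at background mean 2; segment saturation ~ U(0.85, 0.99) except two
planted low-quality TME segments (saturation 0.5), mirroring a 32 → 30
TME QC filter.

Tumor phenotypes (non-NE, hybrid-NE, NE) are allocated to regions by
largest-remainder quota of the configured fractions (default 1/3 each) —
a designed cohort rather than an iid draw, so cluster sizes are stable
across seeds. Each phenotype owns an exclusive gene program
(40 genes each; activation folds 16 / 10 / 8 for non-NE / hybrid / NE).
The unequal folds mirror the empirical asymmetry of real SCLC segment
data, where the non-NE transcriptome is by far the most distinct, and they
fix the PCA geometry: PC1 separates non-NE from the rest, PC2 separates
hybrid (positive) from NE (negative), which is the geometry the
PC-contribution extraction rule presumes. Hybrid co-expression of NE and
non-NE genes at intermediate levels is planted on two additional 12-gene
shared groups (fold 4 in the owning phenotype, fold 2 in hybrid) that are
not part of the signature ground truth; planting the co-expression on the
exclusive programs themselves would place the NE program on PC1− where the
extraction rule cannot recover it.

TME segments are Dirichlet mixtures (concentration 60) over 8 cell types
whose baseline composition depends on the paired tumor's phenotype —
hybrid TME is CAF-dominated (55%), non-NE TME immune-rich, NE TME
intermediate — blended with the uniform composition by
`mixing_link_strength` (default 0.8; 0 decouples composition from
phenotype). Reference profiles give every cell type a 15-gene marker block
(20×), stromal genes elevated in CAF/endothelial and immune genes in
immune types (6×), plus mild lognormal jitter so profiles are not
collinear. Tumor segments mix the phenotype profile with their region's
TME mixture at purity ~ U(0.90, 1), matching the high segment purities of
pan-CK+ selections. Five active ligand-receptor pairs are upregulated
(6×) in non-NE regions, planting the higher interaction load of non-NE
ecosystems.

Survival cohorts draw standard-normal scores, multiply an exponential
baseline hazard (0.03/month, a ~23-month median consistent with advanced
SCLC) by the true HR (default 2.09) above the score quantile (default
0.75), and censor independently (exponential 0.01/month, administrative
cutoff 60 months, ~25–30% censoring). A cohort with zero events raises.

All randomness flows through PCG64 generators seeded with
(seed, substream) pairs; a fixed seed reproduces identical bytes.

**What the generator does not emulate:** spatial coordinates and
neighborhood effects; probe-specific efficiency and sequence biases;
batch/slide effects; gene-gene correlation beyond the planted programs and
mixtures; non-exponential hazards. Passing the recovery suite therefore
shows the algorithms are correct and well-calibrated under the planted
model, not that real SCLC data will separate as cleanly.

## Problem sizes and numerical choices

The validation suite runs the full pipeline at 1,000 genes × 72 segments
(500 HVGs), 50 independent cohorts for clustering recovery, 500 cohorts
for Cox HR recovery, 1,000 for log-rank type-I calibration, and 20 for
differential-interaction power — sizes chosen so each property is measured
with comfortable Monte-Carlo margin while a full run stays in the
single-digit minutes on one CPU. Tolerances: ssGSEA matches its
brute-force oracle to 1e-10; noiseless deconvolution is exact to 1e-6
(solver tolerance); OLS recovery to 1e-8; Q3 equalization is asserted at
relative 1e-9. Degenerate inputs (all-identical k-means input, zero-variance
PCA, constant survival scores, fully censored cohorts, zero-overlap gene
sets) raise or are flagged rather than silently producing numbers.
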