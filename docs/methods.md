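# Methods

This note documents the models, estimators and numerical conventions
implemented in `leukotype`, the defaults behind them, and what the
synthetic-data tests do and do not demonstrate.

## Data model and assumptions

All layers share opaque string sample identifiers; expression defines the
master sample list and every other layer must be a subset (an explicit
`intersect` flag permits silent restriction, otherwise mismatches are
errors). Expression is TPM (or log2(TPM+1), tracked by a flag); downstream
statistics always operate on log2(TPM+1). Methylation is consumed as β
values in [0, 1]; the upstream array QC (detection p, bead counts, SNP and
sex-chromosome probe removal) is assumed done, and missing β values are
rejected rather than imputed. Mutation records are per-variant rows with a
trinucleotide context whose middle base must equal the reference allele;
variant-allele-fraction filtering (> 0.5% by default) happens at load
time. Gene identifiers are never remapped; the mRNA/lncRNA annotation is
caller-supplied (with mRNA as the default class) because biotype
assignment is cohort-specific.

## Feature selection

Variability is the unscaled MAD of log2(TPM+1) — log space stabilizes the
heavy right tail of TPM, and MAD is insensitive to the outlier samples
common in leukemia expression data. "Top 1000 per class" is interpreted
per gene class (1000 mRNA + 1000 lncRNA) so lncRNAs are not crowded out by
the generally higher-variance mRNAs; a `combined_pool` flag gives the
single-pool alternative. Ties at the cutoff break lexicographically by
gene id so selections are order-independent. Mutation features are binary
per gene × sample (a gene counts once per sample regardless of variant
multiplicity) and the prevalence denominator is the full cohort sample
list — configurable, since a prevalence computed over only-mutated samples
would be inflated. The rate threshold is strict (> 0.03).

## Consensus subtyping

The ensemble registry implements six classical partitioners plus an
optional affinity-fusion member, rather than cloning any particular
integrative-clustering toolbox roster — the consensus mechanism, not the
member list, is the method:

1. k-means on z-scored continuous features concatenated with
   unit-variance-scaled binary mutation columns;
2. Ward hierarchical clustering on the same matrix;
3. PAM (alternating assign/update, best of 5 restarts) on a mixed
   distance: the mean of the Spearman-correlation distance on the
   continuous block and the Jaccard distance on the binary block, which
   keeps both layers influential without tuning a weight;
4. spectral clustering on a Gaussian-kernel affinity
   exp(−d²/2σ²) with σ = median pairwise Euclidean distance;
5. a Gaussian mixture with per-component diagonal covariance (scikit-learn
   offers diagonal or shared-full but not shared-diagonal covariance;
   per-component diagonal is the closest member of that family), labeled
   by maximum responsibility;
6. NMF in the consensus-clustering orientation: genes × samples, per-gene
   standardized then shifted nonnegative, with a sample labeled by its
   dominant coefficient factor. (Factorizing the transposed matrix instead
   lets a magnitude factor absorb every sample, which is why this
   orientation is the field's convention.)
7. (`snf`, optional) per-layer Gaussian affinities fused by iterative
   cross-diffusion, then spectral partitioning.

Any empty cluster is repaired deterministically by moving the sample of
the largest cluster farthest from its centroid. The consensus matrix is
the co-assignment fraction over members; final labels are the k-cut of
average-linkage clustering on 1 − M, renumbered by decreasing size (ties
by smallest contained sample index) so outputs are deterministic.

**Choice of k.** CPI(k) is defined in this package as the mean pairwise
adjusted Rand index between the base partitions at k — the index is named
but never defined in the consensus-subtyping literature this workflow
follows, so an exactly testable definition is fixed here. The gap
statistic uses Tibshirani's uniform-over-range reference (B = 50 by
default, 20 in the pipeline defaults) with W_k the pooled within-cluster
sum of squares of a k-means partition; the reported standard error is
sd·√(1+1/B). k maximizes the mean rank of the two curves, with one
refinement: gap values within one reference standard error of the curve's
maximum are assigned a shared (average) rank. Gap curves plateau past the
true k, and values statistically indistinguishable from the plateau
maximum should not outrank its onset; without this the selection
systematically drifts one k too high. Remaining ties resolve to the
smaller k. Silhouettes are computed on the consensus distance (singleton
clusters score 0).

## Signatures, GSEA and projection

The moderated t is the single-factor special case of empirical-Bayes
variance shrinkage: pooled per-gene variances s²_g with d degrees of
freedom are fit to a scaled inverse-χ² prior (d₀, s₀²) by moment matching
on log s² (digamma/trigamma inversion by Newton iteration); the posterior
variance (d₀s₀² + d s²)/(d₀ + d) enters the t statistic with d + d₀
degrees of freedom. When the spread of log variances does not exceed
sampling noise, d₀ = ∞ and all genes share s₀². A `prior_df` override
exposes the two limits (0 = ordinary pooled t, ∞ = fully shared
variance), which the tests use for closed-form comparison.

Signature derivation keeps genes with log2FC > 0 and BH-adjusted P < 0.05,
removes genes qualifying for two or more subtypes ("unique" markers are
read as exclusive to one subtype's significant up-set), and keeps the top
50 per subtype by fold change — larger effects make better binary
templates, which is why fold change rather than P ranks the list.

Preranked GSEA is the weighted Kolmogorov–Smirnov running statistic (hit
increments ∝ |score|^w, default w = 1; miss decrements uniform; ES is the
signed maximum deviation). Because the input is a preranked list, the null
permutes gene labels (random hit positions); NES divides ES by the mean
|null ES| of matching sign and the empirical p uses +1 smoothing.

NTP builds binary templates over the disjoint union of marker genes.
Sample profiles restricted to that universe are standardized
*within-sample* — this makes classification of a single sample possible
and renders the call invariant to any positive affine transform of the
profile, which is the package's compensating choice for cross-platform
batch effects in place of cohort-level correction (batch correction per se
is out of scope). Templates are mean-centered before the cosine, so cosine
distance coincides with 1 − Pearson and a sample matching a template's
standardized pattern sits at distance exactly 0. Significance resamples
random gene sets of the template's size from all measured genes; samples
failing the FDR cutoff keep their argmin label but are flagged.

## Microenvironment scoring

Population abundance is the arithmetic mean of log2(TPM+1) over a marker
set; default marker GMTs for the 8 immune + 2 stromal populations ship as
editable data files and any GMT can replace them. Orientation scores are
geometric means of TPM+1 (pseudocount +1 handles zeros and makes an
all-zero profile score exactly 1); the seven orientation gene lists
(immunosuppression, T-cell activation, T-cell survival, Tregs, MHC-I,
myeloid chemotaxis, TLS) are hard-seeded from the literature. The
single-sample enrichment score ranks genes within a sample (rank value N
for the highest), accumulates the rank^α-weighted in-set ECDF minus the
out-set ECDF (α = 0.25), averages over positions, and subtracts the
uniform-placement baseline computed from the weights alone — the weighting
otherwise gives every random set a small positive offset; centering
removes it without affecting orderings, monotone-transform invariance or
the extremal property. IES/SES apply this score to immune/stromal gene
sets; the tumor-purity calibration of the original estimation tool is out
of scope.

## Methylome

CIMP probe selection restricts to CpG-island probes, drops probes with
mean normal β > 0.9 (near-saturated background), and keeps probes with
tumor β SD > 0.25. The SD filter uses tumors only by default
(`sd_on_all_samples` gives the pooled alternative — the source protocol is
ambiguous on this point). Epi-clusters are the 2-cut of Ward clustering on
tumor β profiles; the cluster with greater mean β is CIMP+, and exact
equality of means is an error rather than an arbitrary orientation.
Differential methylation tests M-values log2(β/(1−β)) with β clipped to
[0.001, 0.999] (configurable) to avoid infinite values, reusing the
moderated-t engine; the reported effect is Δβ because M-value effects are
hard to interpret. The default Δβ threshold is 0 (the upstream tool's
"default settings" are not reproducible verbatim outside the array
pipeline, so only the FDR filter is applied unless a Δβ floor is
requested). Region composition contrasts DMPs against a background probe
set per CGI class and region flag with two-sided Fisher tests, BH-adjusted
within direction.

## Mutational signatures

SBS-96 counting keeps single-base substitutions with nonsense/missense/
silent effects, reverse-complements purine-centered records into the
pyrimidine frame, and tallies the canonical 96 categories (six
substitution classes × 16 flanking contexts). Exome-to-genome
renormalization multiplies each category by its trinucleotide's
genome/exome frequency ratio, supplied as a data file (computing ratios
from a reference genome is out of scope); a synthetic example ratio table
ships with the package. Exposure fitting normalizes the spectrum,
solves nonnegative least squares against the catalog, iteratively zeroes
signatures below `min_weight` (default 0.06, the conventional refitting
cutoff) and refits until stable; weights are renormalized only if their
sum exceeds 1, and the residual is 1 − cosine(reconstruction,
observation). The catalog is user-supplied; the packaged
`toy_sbs_catalog.tsv` contains five synthetic, well-separated signatures
(SynSig1–5) for tests and examples, not COSMIC entries.

## Survival and tabular statistics

Kaplan–Meier, log-rank and Cox regression delegate to lifelines; Cox uses
Efron tie handling, which behaves better than Breslow under the heavy ties
of monthly follow-up resolution. The r×c Fisher exact test enumerates all
margin-fixed tables and sums probabilities no larger than the observed
table's (the probability-mass two-sided convention of standard statistical
software); 2×2 tables shortcut to scipy, which uses the same convention.
Totals are capped at 10⁴. Kruskal–Wallis uses the tie-corrected H with a
χ² reference. BH adjustment is the step-up procedure with monotonicity
enforcement, capped at 1.

## Synthetic cohorts

The generator plants K subtypes (default 3, n = 120, equal proportions by
largest-remainder rounding) with:

* expression: per-gene log2 baselines ~ N(3, 1.5²) with N(0, 1) sample
  noise; each subtype's 100-gene marker block shifted by +2 log2 units
  (the generator's defaults are the package's study conditions; no
  effect-size estimates exist to copy, so defaults were chosen once as a
  clearly separable but noisy regime and left alone). TPM = 2^x − 1 so
  that log2(TPM+1) recovers the simulated value exactly. Expression is
  log-normal with additive log2 effects rather than negative-binomial
  counts because the pipeline consumes TPM, not counts.
* mutations: Bernoulli gene × sample hits, background rate 0.03, three
  enriched genes per subtype at 0.45, with random contexts/effects and
  VAF ~ U(0.05, 0.6);
* methylation: CIMP+ samples (subtype 3 by default) draw promoter-island
  probes from Beta(8, 2) and enhancer probes from Beta(2, 8); other
  tumors are reversed; background probes Beta(3, 3). Normal panels put a
  configured fraction of island probes near Beta(45, 2) (mean ≈ 0.96) to
  exercise the normal-background filter;
* survival: exponential event times with per-subtype hazards
  (0.04, 0.08, 0.012 events/month) and independent U(0, 60) censoring —
  the simplest mechanism satisfying the noninformative-censoring
  assumption of the Kaplan–Meier estimator;
* microenvironment: subtype 1 up-shifts endothelial (+1.5) and fibroblast
  (+1.0) marker blocks, emulating an angiogenic phenotype.

One global seed spawns independent per-layer substreams, so layers can be
regenerated independently and runs are byte-identical.

**What the synthetic tests show.** They demonstrate that each estimator
recovers the structure it targets at realistic noise, that the pipeline's
selections (k, signature, CIMP split) are stable across seeds, and that
the error rates of the tests are calibrated. They do not emulate
library-size artifacts, probe cross-reactivity, subtype-correlated
censoring, gene–gene correlation beyond block structure, or continuous
subtype gradients — performance on real cohorts is expected to be lower
and must be validated there.

## Problem sizes used in the packaged checks

The test suite and acceptance script run the discovery path at n = 120
samples with 2000 simulated genes, 300 top-MAD features per class, k
candidates 2–5 and B = 10 gap references; recovery claims aggregate 20
seeds, and calibration checks use 1000 replicates (10 × 1000 genes for
the moderated t). These sizes were chosen so the whole suite re-runs in
about a minute while leaving every statistical margin (ARI ≥ 0.9,
type-I error in [0.03, 0.07]) intact.

## Known limitations

* The base-partitioner roster is a representative classical set, not a
  reproduction of any specific integrative-clustering package; consensus
  labels on real data will differ in detail from such tools.
* CPI is this package's fixed definition (mean pairwise ARI); other tools
  compute stability indices differently.
* NTP confidence defaults (FDR < 0.05 on the resampled null) are a
  convention; no external standard exists for the cutoff.
* The r×c Fisher test is exact but exponential in table size; large
  sparse tables should be collapsed first.
* EFS endpoints are consumed precomputed; the composite event-time origin
  for non-remission patients is a cohort-level decision made upstream.
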