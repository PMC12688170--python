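# leukotype

Multi-omics consensus subtyping for adult B-cell acute lymphoblastic
leukemia (B-ALL) cohorts.

Adult B-ALL is clinically heterogeneous: patients with the same cytogenetic
diagnosis (Ph-positive, Ph-negative, Ph-like) can differ widely in
microenvironment composition, methylation state, mutational processes and
outcome after transplantation. `leukotype` implements a reusable pipeline
for discovering and characterizing molecular subtypes from bulk multi-omics
data — expression (TPM), somatic mutations, methylation β values and
clinical follow-up — and for projecting new cohorts onto an established
subtype system from expression alone. It is written for computational
hematology/oncology groups who want the full workflow as tested,
scriptable Python rather than a collection of R one-offs.

## Method

**Feature space.** The top *n* most variable mRNAs and lncRNAs by the
unscaled median absolute deviation, MAD(g) = median |x<sub>g</sub> −
median x<sub>g</sub>| of log2(TPM+1), per gene class (default 1000 each),
plus binary indicators for genes mutated in strictly more than 3% of
samples.

**Consensus ensemble.** A registry of base partitioners (k-means, Ward,
PAM on a mixed Spearman/Jaccard distance, spectral, diagonal-covariance
Gaussian mixture, consensus-orientation NMF, optional affinity fusion) is
run at each candidate k. Their agreement forms the consensus matrix
M<sub>ij</sub> = (fraction of partitions co-assigning samples i and j);
final labels come from average-linkage clustering of D = 1 − M. The number
of subtypes is chosen by the mean rank of two curves: CPI(k), the mean
pairwise adjusted Rand index between base partitions, and the Tibshirani
gap statistic Gap(k) = E[log W\*<sub>k</sub>] − log W<sub>k</sub> with a
uniform-over-range reference. Silhouette widths s(i) = (b−a)/max(a,b) on
the consensus distance report per-subtype cohesion.

**Signatures and projection.** One-vs-rest differential expression uses a
moderated t statistic (per-gene variances shrunk toward an
empirical-Bayes prior estimated from the variance distribution); the
subtype signature takes, per subtype, the top 50 upregulated markers
(adjusted P < 0.05, Benjamini–Hochberg) that are *unique* to that subtype,
ranked by log2 fold change. Nearest-template prediction (NTP) assigns any
sample to the subtype whose binary marker template minimizes the cosine
distance of the within-sample standardized log2(TPM+1) profile, with
significance from a resampled null of random gene sets.

**Characterization.** Microenvironment scoring (marker-mean population
abundances, geometric-mean functional orientation scores, rank-based
immune/stromal enrichment), CpG-island methylator phenotype (CIMP) calling
with differential methylation on M-values and region enrichment, SBS-96
mutational-signature exposures by nonnegative least squares with
minimum-weight pruning, and survival analysis (Kaplan–Meier, log-rank,
Cox with Efron ties, r×c Fisher exact, Kruskal–Wallis).

A `synthetic_cohort` module generates cohorts with planted subtype
structure across all four layers, so the entire pipeline is testable
without any restricted-access data.

## Worked example

```sh
leukotype simulate --seed 3 --out-dir run
leukotype features --expr run/expression.tsv --mutations run/mutations.tsv \
    --n-per-class 100 --out run/feats.tsv
leukotype cluster --expr run/expression.tsv --features run/feats.tsv \
    --mutations run/mutations.tsv --k-min 2 --k-max 4 --b-reference 5 \
    --seed 3 --out-dir run/clus
leukotype signatures --expr run/expression.tsv \
    --labels run/clus/subtype_labels.tsv --out run/sig.tsv
leukotype ntp --expr run/expression.tsv --signature run/sig.tsv \
    --n-null 200 --out run/ntp.tsv
leukotype cimp --beta run/beta.tsv --groups run/beta_groups.tsv \
    --annot run/probe_annotation.tsv --out-dir run/cimp
```

prints

```
wrote cohort (n=120, k=3) to run
wrote 225 features to run/feats.tsv
selected k=3, mean silhouette 0.997
wrote 150-gene signature to run/sig.tsv
classified 120 samples
CIMP+: 40, CIMP-: 80
```

The simulated cohort has three planted subtypes of 40 samples each; the
consensus ensemble selects k = 3 with near-perfect consensus cohesion
(mean silhouette 0.997 on 1 − M). Signature derivation finds 50 unique
upregulated markers per subtype (150 template genes total), and the CIMP
caller assigns exactly the 40 samples of the methylator subtype to CIMP+.
The same steps are available as a single `leukotype run-all --config
config.yaml` invocation, and `leukotype project` applies a saved signature
to an external expression cohort.

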