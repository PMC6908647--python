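# Methods

## Data model

Beta values β ∈ [0, 1] are methylated-fraction estimates per CpG probe and
sample; missing entries are allowed on input and removed by QC + imputation
before any test. Probe annotation follows 450K-manifest conventions: each
probe has a CGI relation (Island / N_Shore / S_Shore / N_Shelf / S_Shelf /
OpenSea) and zero or more gene links, each with a region class (TSS1500,
TSS200, 5UTR, 1stExon, Body, 3UTR); semicolon-joined parallel lists encode
multi-gene probes; coordinates are 1-based. "Promoter" means
TSS200 ∪ TSS1500 throughout (configurable); operationalizing the promoter by
manifest region class rather than coordinates keeps the pipeline
annotation-driven and matches how array studies report genomic-context
summaries.

## QC and imputation

Probes are removed for (in precedence order) SNP overlap, chromosome X, or a
missing fraction strictly greater than `max_missing` (default 0.10, i.e. a
probe at exactly 10% is kept). Each probe is counted under its first
matching reason so the QC report conserves the input count. Missing values
are replaced by the per-probe mean **within condition** when both conditions
have ≥ 3 samples, else the global probe mean. 450K probes are not an ordered
series, so a time-series interpolator would be ill-posed here; mean
imputation within condition is unbiased for the group means that every
downstream test consumes, which is the property that matters. Whether to
impute within condition or globally is a genuinely open choice; the
within-condition default is documented and the global fallback covers tiny
groups.

## Differential methylation

Two-sided Wilcoxon rank-sum per probe. When both groups have ≤ 8 samples the
p-value is exact: the null distribution of the (midrank) rank sum is
enumerated over all C(n₁+n₂, n₁) group assignments, which handles ties
without approximation. Larger designs use the tie-corrected normal
approximation (midranks, continuity correction); constant probes get p = 1.
FDR is Benjamini–Hochberg step-up. A CpG is a DMC when |Δβ| > 0.2 (strict)
and FDR < 0.05; FDR is computed on all tested probes and both filters are
then applied (the alternative — Δ filter before adjustment — is a config
knob, not the default). Direction is the sign of Δβ.

## Differential expression

TMM factors: the reference sample is the column whose 75th percentile of
count fractions is closest to the mean such percentile; per sample,
M = log2 library-normalized ratio and A = mean abundance are computed over
genes nonzero in both columns, doubly trimmed (30% per tail on M, 5% on A),
and combined by inverse-(delta-method)-variance weights; factors are
rescaled to geometric mean 1. Because M-values are computed on
library-size-normalized counts, a column that is a scaled copy of another
gets factor 1 — sequencing depth lives in the library size, composition bias
in the factor, and the GLM offset log(library_size × factor) uses both
exactly once.

The NB GLM is fit per gene with log link, two-group design and that offset;
fitting is Fisher scoring vectorized across all genes simultaneously. A
single common dispersion α is chosen to maximize the summed profile
log-likelihood over genes (bounded scalar search on log α ∈ [1e-6, 10],
tolerance 1e-6). The group coefficient is tested by a likelihood-ratio χ²
with 1 df; log2 FC = coefficient / ln 2. All-zero genes are flagged and
reported as (log2 FC 0, p 1). Common dispersion + LRT is deliberately the
smallest defensible NB machinery: tagwise/trended dispersion and
quasi-likelihood F-tests are established refinements but add estimator
choices the rest of the pipeline does not depend on; with the common
dispersion the type-I error at α = 0.05 calibrates to 0.05 ± 0.02 in the
acceptance simulation. DEGs: |log2 FC| > 1.5 (strict) and FDR < 0.05.

Note on parameter-recovery experiments: when *every* gene carries the
planted fold change, data-driven offsets absorb the global shift (that is
what normalization is for), so the fold-change recovery experiments condition
on the true flat normalization; the type-I experiment uses TMM as in
production.

## CIMP consensus clustering

Variable probes: CGI-island promoter probes with tumor SD > 0.2 (strict) and
normal mean β < 0.05. Consensus clustering: `n_reps` subsamples of 80% of
samples without replacement, K-means (Euclidean, k-means++, 10 restarts,
per-rep derived seed) on each; consensus(i,j) = co-clustered count /
co-sampled count; final labels from average-linkage hierarchical clustering
of 1 − consensus cut at k. k = 3 is the replication preset (CIMP-high /
-intermediate / -low); a PAC (proportion of ambiguous clustering) utility
supports choosing k but is not used by the preset. The library default is
1000 repetitions; the pipeline preset and tests use 50–200, which on the
synthetic cohorts already yields binary consensus and ARI = 1 against the
planted partition — the generator's cluster offsets (0.15/0.45/0.75 at
Beta-noise SD ≈ 0.06) are ~5 SDs apart, comfortably past the ≥ 3 SD regime
where exact recovery is expected.

Cluster–clinical association: r×c Fisher exact test, summing the
probabilities of all margin-consistent tables no more probable than the
observed one; tables up to 2×3 (either orientation) or total ≤ 30 are
enumerated exactly, larger tables use 100,000 Patefield-sampled tables
(fixed seed) with the Monte-Carlo standard error reported. Cluster
methylation differences use classical one-way ANOVA; zero within-group
variance reports F = ∞ with p at the smallest positive float.

## Integration

Expression for correlation is log2(CPM + 1) on TMM-effective library sizes
(the choice of expression transform is a config-level decision; logCPM is
the conventional one). Local analysis: Pearson r per promoter-CpG → own-gene
pair on shared samples; distant analysis: CpGs of differentially methylated
and expressed genes against all DEGs, excluding each CpG's own gene — a
"distant" pair with itself is a contradiction in terms, so self-pairs are
excluded by definition. Significance: |r| > 0.3 and BH-FDR < 0.05, with BH
applied within each call's pair universe, never pooled across the local and
distant runs. Genes are classified positive / negative / both by the signs
of their significant pairs (both requires at least one of each sign).
Constant vectors are skipped and counted. Gene-set enrichment is the
hypergeometric upper tail per GMT set with BH across sets — a deliberately
generic over-representation utility.

## Marker discovery

Candidates = hyper-DMCs lying in promoter regions of hyper–down genes.
Specificity screen: a candidate survives only if it is a DMC (either
direction, same thresholds) in zero other cancer types; the filter is
monotone in the set of screening tables. Information gain uses equal-width
binning of β on [0, 1] (default 10 bins; bin count is a config key) and is
reported in bits: IG = H(X) − H(X|Y), i.e. the mutual information of the
binned joint — non-negative and bounded by min(H(X), H(Y)). The selection
cutoff is IG > 0.3, strict, with candidates ranked by descending gain.

SBFS starts from the full filtered set and repeatedly removes the single
feature whose removal maximizes stratified-CV accuracy of the ridge-logistic
classifier (5-fold default inside selection; folds fixed from the seed and
shared across subset evaluations). Ties on accuracy remove the feature with
the lowest IG, then the lexicographically smallest probe id. Every evaluated
subset is recorded and the returned panel is the global accuracy maximum
over all of them — not the point where accuracy first drops — with ties
going to the smaller subset, then lexicographic order. With fully specified
tie-breaks the whole trajectory is reproducible bit for bit from the seed.

## Classifier and evaluation

Logistic regression is fit by Newton iterations (convergence when the
largest coefficient change < 1e-8, cap 100 iterations) with an L2 ridge of
1e-4 on the coefficients only. The ridge matters: perfect markers make the
classes separable and the unpenalized MLE diverges; 1e-4 leaves estimates
essentially unshrunk on non-separable data while guaranteeing existence.
Confusion counts use a probability cutoff of 0.5; AUC is the rank
(Mann–Whitney) probability with ties counted ½, so it is cutoff-free and
invariant to monotone score transforms. Cross-validation is stratified
(folds reduced with a warning when a class is smaller than the fold count),
with confusion pooled over held-out folds and AUC from pooled held-out
scores. Reports carry per-class rows plus the class-size-weighted average
row, matching the standard per-class performance-table layout. "Sensitivity"
is the tumor TP rate and "specificity" the normal TP rate.

## Synthetic cohorts: what they emulate, and what they don't

Beta noise is Beta(μκ, (1−μ)κ) with κ = `beta_precision` (default 50),
giving the bounded, heteroskedastic, near-0/near-1 bimodal shape of array
beta values. Defaults: 3 cancer types × 100 tumors / 100 normals, 2000
probes, 300 genes, 4 target-specific + 6 shared markers at Δβ = 0.4 over
normal baselines of 0.05–0.15, a 60-probe CIMP block (normal mean 0.03,
three tumor-cluster offsets), 40 + 40 hyper/hypo background DMCs in gene
bodies, 30 directly DE genes at |log2 FC| = 3, NB dispersion 0.1, library
size factors uniform in [0.7, 1.3], and 2% missingness (MCAR per cell).
These sizes are chosen so that every recovery experiment is decisively
powered at desk scale: Δβ = 0.4 at n = 50/50 puts planted DMCs far beyond
the 0.2 call threshold, and the coupled expression shift
(coupling −3 nats per unit β, i.e. ≈ −1.7 log2 units at Δβ = 0.4) clears the
DEG cutoff with a wide margin. Expression coupling acts on the log NB mean,
log μ = baseline + coupling × (β − β̄), so its sign and magnitude are
directly controllable and induce the negative methylation–expression
correlations the integration stage measures. Clinical covariates
(histology, HPV status, HPV clade) are sampled with cluster-dependent
frequencies so the Fisher association test has true signal.

Not emulated: realistic genomic coordinates or probe density, cross-reactive
probes, batch/plate effects, cell-type composition, copy number, HPV
integration biology, and correlated (non-MCAR) missingness. Passing the
recovery tests therefore demonstrates the pipeline's statistical machinery
under its stated model, not robustness to those real-data artifacts.

## Numerical conventions and degenerate inputs

All thresholds are strict inequalities exactly as stated above (a probe at
Δβ = 0.2, SD = 0.2, IG = 0.3 or log2 FC = 1.5 is excluded). Determinism:
every stochastic stage (simulation, missingness, consensus subsampling, CV
folds, SBFS, Monte-Carlo Fisher) consumes a `numpy` Generator derived from
an explicit integer seed, and identical seeds give bit-identical outputs.
Degenerate cases are defined, not exceptional: all-tied rank tests give
p = 1, constant correlation vectors are skipped and counted, all-zero genes
are flagged neutral, precision with no positive predictions is 0, and the
F-measure of (0, 0) is 0. Errors name the offending probe, sample or stage.

## Limitations

Common (not tagwise) NB dispersion; class-based promoter definition rather
than coordinate windows; no DMR-level (region) calling; the specificity
screen treats other-cancer DMC tables as exchangeable evidence without
effect-size weighting; greedy SBFS does not guarantee the global optimum
over all subsets (the exhaustive-search equivalence holds on the tested
scales); and the Fisher Monte-Carlo p-value carries sampling error reported
as a standard error rather than an exact bound.
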