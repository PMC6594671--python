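# Methods

`dietsurv` re-implements, as a tested library, the transcript-level
analysis pattern used in diet-intervention liver-cancer studies: score
tumor samples for opposing metabolic programs (fatty-acid β-oxidation,
FAO, versus glycolysis — the two arms of the Randle cycle), stratify
patients on those scores, compare survival nonparametrically, and, in a
six-group mouse design, ask which tumor-dysregulated transcripts a
high-fat diet pushes back toward the normal-liver baseline.

## Expression scales

All analyses consume FPKM-like non-negative expression. Two scales are
explicit throughout: raw `fpkm` and `log2p1`, the incremented log2
transform `log2(x + pseudocount)` with pseudocount 1.0 by default (the
convention of the common pan-cancer expression exports). Pathway scores,
fold-changes, differential tests and rescue indices all operate on the
`log2p1` scale; heatmap scaling and per-sample sum-normalization
back-transform to FPKM first. Missing values are a hard error — the
analyses assume complete matrices, and silent imputation would bias
panel means.

## Pathway scores and stratification

The score of sample *s* for panel *P* is the unweighted mean of the
`log2p1` values of the panel genes present in the matrix. Panel genes
absent from a matrix are dropped with a warning rather than imputed as
zero, because zero-filling would make scores depend on annotation
coverage. Consequences tested: scores are invariant to gene order and to
genes outside the panel, and adding a constant to all values shifts
every score by that constant.

Median split: scores strictly above the cohort median are `high`; ties
go to `low`. The tie rule is a choice (the field convention says only
"above or below the median"); sending ties to `low` is deterministic and
conservative for claims about the high-expression group. Quadrant
groups intersect two independent median splits: `FAO_high_gly_low`
(above-median FAO, at-or-below-median glycolysis), the mirror group, and
`other`. A stricter outer-quartile rule is available behind
`RunConfig.quadrant_rule="quartile"` for analyses phrased in terms of
extreme quartiles. Both stratifiers are invariant under strictly
monotone transforms of the scores.

Heatmap values divide each gene's FPKM by the mean FPKM of the
reference panel in the same sample and take log2, so per sample the
panel satisfies `mean(2**H) = 1` exactly (checked to 1e-9). The
reference defaults to the displayed panel (per-pathway heatmaps) and can
be switched to all genes. An `epsilon` guard (default 0) is available
for matrices with exact-zero panel means.

## Survival

Survival time is `max(days_to_death, days_to_last_followup)` over the
fields present; the event indicator is 1 exactly when a days-to-death
value exists. Day 0 is valid (same-day event).

The Kaplan–Meier estimator and the Mantel–Cox log-rank test are
implemented from the standard formulas rather than delegated, so their
small-sample behavior is testable against a brute-force permutation
oracle; the `lifelines` implementations serve as an independent
cross-check in the test suite (agreement to 1e-10). Ties at an event
time use the hypergeometric variance with all tied events counted at
that time. The k-group statistic inverts the (k−1)-dimensional
covariance submatrix (pseudo-inverse fallback for singular cases) and is
referred to chi-square with k−1 df. For small samples
`logrank(..., method="permutation")` resamples group labels and reports
the add-one-corrected tail fraction of the observed statistic. Pairwise
comparisons are provided unadjusted, matching the common practice of
reporting unadjusted pairwise p-values alongside the omnibus test.
Median survival is the smallest time with S(t) ≤ 0.5 and is undefined
(None) when the curve never reaches 0.5.

## Differential expression and rescue classification

The default two-group test is a per-gene Welch unequal-variance t-test
on `log2p1` values with Benjamini–Hochberg q-values (Bonferroni by
config). This is a deliberate substitute for count-based
negative-binomial machinery: the pipeline consumes FPKM-scale matrices,
not read counts, and the downstream logic (directional overlap, rescue
calling) only needs a calibrated per-gene test with FDR control.
Significance requires `q < 0.05` and `|log2FC| ≥ 1` by default; both
gates are configurable. Genes constant in both groups are flagged
`degenerate` (p = 1 when the constant means agree, p = 0 when they are
constant but different).

Directional overlap of two significant sets counts A-only, B-only,
shared-same-direction and shared-opposite-direction genes; the headline
percentage is shared-same-direction over the size of the union.

The rescue (normalization) index of a tumor-dysregulated gene under a
diet is

    r = (mean_HFD_tumor − mean_NFD_tumor) / (mean_liver − mean_NFD_tumor)

on the log2 scale: 0 = no movement back toward liver, 1 = complete
normalization. A gene is dysregulated when NFD-tumor vs NFD-liver is
significant; rescue additionally requires the HFD-tumor vs NFD-tumor
contrast to be significant with the opposite sign. Categories:
unrescued (r < 0.3), partial (0.3 ≤ r < 0.8), complete (0.8 ≤ r ≤ 1.5),
overshoot (r > 1.5). The 0.3/0.8 cutoffs quantify "partially or
completely normalized", which has no standard numeric definition; they
are exposed in `RunConfig` and echoed into outputs. The overshoot bound
1.5 marks diets that push expression well past the liver level. r is
invariant to adding a constant to all three group means; genes with
coincident liver and NFD-tumor means (denominator ≈ 0) are flagged and
excluded. `normalized_by_both` requires both diets to land in
{partial, complete}.

## Embedding, clustering, importance

Panel expression is embedded in 2-D with t-SNE (scikit-learn backend;
the contract is determinism given the seed plus the recorded
parameters, not a bespoke implementation). Defaults: perplexity 30,
learning rate 200, up to 10,000 iterations; the sample count must be at
least 3× the perplexity. FPKM input is first normalized per sample to
its column sum. Cluster strata come from k-means on the embedding with
a fixed seed (visual cluster identification is not reproducible);
`k="auto"` maximizes mean silhouette over k = 2..6, and labels are
ordered by decreasing cluster size. Cluster-wise survival reuses the
log-rank machinery (omnibus + pairwise).

Transcripts "most determinant" of the cluster patterns are ranked by
permutation importance of a random-forest classifier predicting cluster
labels from panel expression (mean accuracy drop over 20 shuffles of
each gene's column). Permutation importance was chosen over
impurity-based importance because impurity scores differ across tree
implementations and would not be comparable across environments.

## Synthetic data

The cohort generator emulates the statistical structure the downstream
stages assume, not RNA-seq noise. On the `log2p1` scale, gene *g* in
sample *s* is

    x[g,s] = μ_g + shift[cluster(s), g] + σ·(√ρ·F_p(s) + √(1−ρ)·ε[g,s])

with per-gene means μ_g uniform in baseline ± 2 (default baseline 6,
σ = 1, values clipped at 0), a shared standard-normal factor F per
pathway panel inducing within-panel correlation ρ (default 0.5) — F is
the sample's true standardized panel score — and optional per-cluster
per-gene mean offsets with sd Δ (`cluster_shift`). The
`cluster_informative_genes` field restricts cluster offsets to the
first k FAO-panel genes, planting an identifiable set of
cluster-driving transcripts. Survival is exponential with hazard
`λ0·exp(β_gly·S_gly + β_fao·S_fao)` (λ0 = ln2/730 per day, median ≈ two
years at null) censored by an independent exponential follow-up clock
(4e-4 per day, ≈ 30% censoring at null) — censoring carries no
informative structure, matching the censoring rule it emulates. Times
are rounded to whole days for the clinical table.

The mouse generator builds the six-group design
{liver, tumor} × {NFD, MC_HFD, LC_HFD} with disjoint planted
categories: tumor-dysregulated genes (±δ_t, default 2 log2 units,
alternating sign), subsets rescued by both or one diet (HFD-tumor mean
pulled a fraction r_true, default 0.9, back toward liver), synergy
genes (diet main effect δ_d in HFD livers plus an extra δ_s only in HFD
tumors), and null background. Residuals are Gaussian (σ = 0.25) on the
`log2p1` scale. The truth tables from both generators carry every
planted quantity needed to score downstream calls.

What the generators do *not* model — and hence what passing tests do
not certify on real data: count-level noise (negative binomial,
library-size effects), batch structure, informative censoring,
annotation errors, and gene–gene correlation beyond the single shared
factor per panel.

## Numerical and study-size choices

Monte-Carlo study sizes were chosen to make the checks sharp while the
full suite stays fast: 1000 replicates for log-rank type-I error
(α = 0.05 acceptance band 0.035–0.065), 200 cohorts of n = 400 for
quadrant-contrast power (≥ 90% rejections at β = ±0.7), 50 designs for
rescue recovery (sensitivity ≥ 0.9, specificity ≥ 0.95) and 50 for
driver-gene recovery (all 4 planted drivers in the top 6 ranks in
≥ 90% of seeds, 50-tree forests on n = 100). Embedding studies use 500
t-SNE iterations at n = 150, which stabilizes the toy geometries the
tests plant; real cohorts warrant the 10,000-iteration default. All
acceptance thresholds are fixed a priori by the study design, not tuned.

Degenerate inputs are errors, not silent defaults: all-identical scores
(no informative median), zero panel overlap, all-zero sample columns,
more clusters than samples, single-class labels, and zero total events
in a log-rank comparison.
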