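# Methods

This note documents the models the package implements, the generative
model behind the synthetic cohorts, the numerical conventions, and the
design choices made where more than one defensible option existed.

## Study design being modelled

A paired two-timepoint cohort: each subject (a horse) contributes one
sample at baseline (T0) and one immediately after an endurance effort
(T1), with three layers measured on the same samples — an NMR metabolite
peak table, a gene expression matrix and a miRNA expression matrix, both
on the log2 scale. The pipeline asks three questions: which metabolites
discriminate T1 from T0; which genes and miRNAs respond; and how the
layers hang together (which metabolites are enriched in correlated
metabolic genes, which regulators rewire their co-expression, and how
strongly the tables share structure in a joint factor model).

## Synthetic cohort generator

The generator is the package's test bed: it produces data satisfying
exactly the assumptions the downstream stages test, with the planted
structure recorded as ground truth.

Generative model, per feature and sample:

* **Residuals.** Every feature has a unit-variance residual
  `x = (τ·b + σ·e)/√(τ²+σ²)`, where `b` is a per-horse intercept shared
  by the horse's two samples (`horse_sd` τ, default 0.5) and `e` is iid
  Gaussian (`noise_sd` σ, default 1.0). The intercept creates the paired
  (within-horse) correlation; features are otherwise independent.
* **Metabolites.** Log-intensity is `baseline + 0.25·z`, exponentiated to
  a log-normal peak intensity. For an *active* metabolite,
  `z = ±δ_m·1[T1] + √ρ·L + √(1−ρ)·x` with `δ_m = effect_size_metab`
  (standardized mean difference, default 1.5), `L` a per-sample latent
  factor, and `ρ = latent_coupling`. The 0.25 log-normal scale keeps
  Pearson correlations on the intensity scale within ~2% of the latent
  correlation.
* **Coupled genes.** Each active metabolite owns a dedicated pathway;
  that pathway's genes carry the same latent factor:
  `value = baseline ± δ_g·1[T1] + √ρ·L + √(1−ρ)·x` (with the shift sign
  matching the metabolite's), so each planted (metabolite, gene) pair has
  Pearson correlation with expectation ≥ ρ — slightly above it, because
  the shared T1 shift adds between-class covariance. Placing actives in
  dedicated single-metabolite pathways keeps ground truth unambiguous:
  the rank-sum enrichment test is metabolite-agnostic given the pathway,
  so a decoy metabolite sharing an active pathway would be an intended
  positive rather than a false one.
* **Other DE features.** A random subset of genes reaching
  `frac_de_genes` (and the analogous fraction of miRNAs) shifts by
  `±effect_size_gene` (default 2.0) / `±effect_size_mirna` (default 1.5)
  at T1. With 10 paired horses and BH q < 0.05 these defaults give call
  proportions typical of a strong whole-organism intervention (~30% of
  genes, ~30% of miRNAs); materially smaller effects leave a 10-horse
  cohort underpowered.
* **Regulators.** Each active regulator (a miRNA, or optionally a TF
  gene) has its residual mixed into the *non-coupled* DE genes at T1 only
  with weight `regulator_strength/√K` (default 1.0), producing
  co-expression near 0.7 at T1 and ~0 at T0 — a differential
  co-expression signal for the RIF metrics without disturbing the
  metabolite–gene coupling. Active miRNA regulators are themselves DE and
  receive at least 10 validated targets among the coupled genes in the
  target database; decoy miRNA–target pairs are added at
  `decoy_target_rate`.

Default cohort sizes mirror the emulated design: 10 horses, 54 metabolite
peaks, 362 miRNAs, 11 active metabolites, 5 miRNA regulators; the gene
layer (2,000) is a desk-scale stand-in for a genome-wide microarray.

What the generator does **not** emulate: raw spectra (only binned peak
tables), probe-level microarray structure, heavy-tailed or
batch-structured noise, correlated background genes, imperfect pathway
annotation, or realistic physiology. Passing tests therefore demonstrate
that each method recovers the structure it assumes, under its own
assumptions — not field performance on real cohorts.

## Chemometrics

OPLS is fitted by the NIPALS orthogonal-projections scheme: for each of
`n_ortho` rounds, compute the PLS weight `w ∝ Xᵀy`, its loading `p`, and
remove the component of `p` orthogonal to `w` as an orthogonal score/
loading pair; the final predictive component is PLS on the deflated
matrix. With `n_ortho = 0` the model *is* single-component PLS (verified
against scikit-learn's NIPALS implementation). Orthogonal scores are
uncorrelated with y by construction. Class coding is T0 = −1, T1 = +1, so
positive predictive loadings mean higher at T1.

Conventions and defaults:

* Centering always; unit-variance scaling by default, Pareto by flag.
  Constant columns under scaling are an error naming the column.
* Cross validation: stratified 10-fold, seed-controlled; the OSC filter
  is refitted inside every training fold, so held-out predictions are
  leakage-free. Q² = 1 − PRESS/TSS with TSS the total centered sum of
  squares; RMSEP = √(PRESS/n).
* Permutation validation re-runs the full CV per shuffled label vector
  (identity permutation excluded) and reports observed vs permuted
  R²/Q²/RMSEP as mean ± sd plus the fraction-based p-value on Q².
* Discriminant variables: jack-knife confidence intervals of the
  predictive loadings across CV folds (sign-aligned to the full-model
  loading, variance factor (k−1)/k); a variable is selected when its 95%
  interval excludes zero. This operationalizes "loading different from
  zero" with an explicit, seedable rule.
* **Permutation scheme under pairing.** Both Monte-Carlo tests accept a
  `groups` argument. With per-horse random intercepts, freely permuting
  T0/T1 labels is not exchangeable and the null p-values are visibly
  non-uniform; permuting within horse (the paired sign-flip group) is an
  exact symmetry of the null and restores uniformity. The pipeline always
  passes horse ids; the ungrouped default remains appropriate for iid
  rows.

The interclass test statistic is the between-class share of total
inertia of the (optionally scaled) data cloud, with
`p = (1 + #{perm ≥ obs})/(n_perm + 1)`.

## Differential expression

A paired t-test on within-horse T1 − T0 log2 differences, two-sided, with
BH step-up q-values (via statsmodels) and a q < 0.05 gate. A moderated
option shrinks per-feature variances toward the median variance with a
prior of 3 df, for very small cohorts; the plain test is the default.
All-zero difference vectors are reported as non-significant; zero-spread
nonzero differences get the machine-minimum p and a degenerate flag.

## Enrichment and network

* Correlations between a metabolite's abundance (raw normalized peak
  area, not OPLS-processed) and each DEG are computed across all paired
  samples pooled over T0 and T1 — the T0→T1 contrast is the signal of
  interest and pooling maximizes n. The |r| > 0.5 and p < 0.05 gates are
  strict inequalities and deliberately unadjusted; FDR control happens at
  the metabolite level.
* The hypergeometric universe defaults to every gene on the expression
  platform (configurable to a DEG-only universe for sensitivity
  analyses).
* The Wilcoxon variant uses the exact null distribution when the combined
  sample is ≤ 25 without ties, otherwise the tie-corrected normal
  approximation.
* The two test families are BH-corrected separately across metabolites,
  preserving the "significant in either test" rule at FDR < 0.1.
* miRNA overlay: significant DE miRNAs with ≥ 1 validated target among
  the in-network metabolic genes; the network assembler can require a
  minimum target count (`min_targets`, pipeline default 10) to focus on
  hub regulators.
* Pathway impact: per-metabolite importance is relative betweenness
  centrality (out-degree by flag) normalized to sum 1 within the
  pathway's directed metabolite graph; impact is the summed importance of
  matched metabolites, in [0, 1] and monotone in the matched set.
  All-zero centralities (edgeless graphs) fall back to uniform importance
  with a warning.

## Regulatory impact factors

Condition 1 is T0 and condition 2 is T1, so a positive abundance
difference `d_j = ē1_j − ē2_j` means higher at T0; the sign convention is
stated in the output header. Correlations of a constant regulator are set
to 0 with a warning rather than dropping the regulator. Raw scores and
z-standardized scores are both emitted: the raw values carry the hand-
checkable algebra, the z-scores make regulators comparable across runs.
miRNA regulators are scored by joining the miRNA matrix to the gene
matrix on shared samples.

## Multiple factor analysis

Tables are centered and unit-variance scaled within table (the
quantitative-group convention), then weighted by 1/σ₁; the grand matrix
is decomposed by SVD truncated at numerical rank (axes beyond rank are
arbitrary and never reported). Partial scores use the number-of-tables
scaling, so the table-average of partial scores equals the global score
exactly. Group contributions are the summed squared loadings per table
and dimension (summing to 1 across tables). High-weight variables are
those whose |correlation| with a global axis strictly exceeds the
threshold (default 0.80 — the threshold is a parameter, so a stricter
r² reading of 0.80, i.e. |r| > 0.894, is one argument away). T0 and T1
cohorts are analyzed in separate MFA fits; a two-sample t-test with BH
correction (`group_differences`) supports comparing finishers against
eliminated subjects at baseline, without any claim that this reproduces a
specific published test.

## Numerical choices and degenerate inputs

* Detection in peak filtering means intensity strictly above a
  configurable floor (default 0); the 50% rule is inclusive (exactly half
  survives); filtering is idempotent and never alters retained values.
* Assignment ties (equidistant references) break toward the lower
  reference shift, deterministically.
* Permutation p-values use the (1 + B)/(n + 1) form and never reach 0.
* Empty enrichment input produces an empty network and a run-report flag
  rather than an error; stage failures abort with the stage name and
  retain partial outputs.
* Every stochastic operation takes a seed; the pipeline derives per-stage
  seeds from the top-level seed via `SeedSequence`, and reruns are
  bit-identical (verified by output hashing).

## Problem sizes in the test suite

The suite exercises calibration and recovery at sizes chosen to make the
checks statistically meaningful while keeping the default run light:
null-calibration uses 20-horse cohorts (100 replicates for the interclass
test, 60 for OPLS permutation with 60 permutations each); enrichment
recovery uses 20 seeds of a 30-metabolite/1,000-gene cohort; regulator
recovery uses 50 simulations of 101 miRNAs over 400 genes. The end-to-end
determinism check runs the full pipeline twice at the default cohort size
with the full 999/1,000 permutation counts.

## Known limitations

* The paired t-test is the only DE engine; no empirical-Bayes moderation
  beyond simple variance shrinkage, no covariates or batch terms.
* OPLS supports a single predictive component (two-class y), which is the
  discriminant use case; multi-y or multi-component prediction is out of
  scope.
* The enrichment tests treat metabolites independently; overlapping
  pathway memberships induce correlated tests that BH handles only
  approximately.
* RIF scores rank regulators; they are not effect estimates and carry no
  causal claim.
* The RV coefficient grows toward 1 mechanically as p ≫ n; compare RV
  values only between tables of similar dimensionality.
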