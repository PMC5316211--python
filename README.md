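# omicsweave

Integration of a serum metabolome, a blood transcriptome and a miRNome —
measured on the same individuals before (T0) and after (T1) an endurance
effort — into a single regulatory network, together with the chemometric,
statistical and multi-table machinery the workflow needs and a synthetic
cohort generator with planted ground truth for end-to-end validation.

The package is aimed at systems-biology practitioners working with paired
multi-omic designs (small n, large p) who want each stage of such an
integration to be reusable, testable and reproducible on its own.

## The workflow

1. **NMR peak prep** (`omicsweave.peaks`) — remove single-mass-event peaks
   and peaks detected in fewer than 50% of samples; quantify relative
   abundance as the peak area; assign peaks to reference metabolites by
   nearest chemical shift within ±0.005 ppm.
2. **Chemometrics** (`omicsweave.chemometrics`) — PCA and an interclass
   Monte-Carlo inertia test, then OPLS discriminant analysis: a NIPALS PLS
   component fitted after orthogonal signal correction (OSC) strips
   `n_ortho` components of X-variation orthogonal to the class vector
   y ∈ {−1, +1} (T0 = −1, T1 = +1). Internal validation: stratified
   10-fold cross validation (R², Q² = 1 − PRESS/TSS, RMSEP), label
   permutation (n = 1,000), and jack-knife confidence intervals on
   predictive loadings for discriminant-variable selection. Univariate
   ANOVA with Bonferroni correction complements the model.
3. **Differential expression** (`omicsweave.de`) — paired t-tests on
   within-horse log2 differences with Benjamini–Hochberg control
   (q < 0.05); `PairedDifferential(x, metadata).fit()` returns a results
   object with a `summary()`.
4. **Metabolite–gene enrichment** (`omicsweave.enrichment`) — a
   metabolite's *metabolic genes* are the genes of every pathway it
   participates in. Two tests per metabolite: (i) hypergeometric
   over-representation of metabolic genes among DEGs correlated with the
   metabolite (|r| > 0.5, p < 0.05), and (ii) a one-sided Wilcoxon
   rank-sum test that the metabolic genes' DE p-values are smaller than
   the rest of the transcriptome. BH per test family; enriched if either
   q < 0.1. Significant DE miRNAs with validated targets among the
   metabolic genes are overlaid, everything is assembled into a typed
   network (GraphML/SIF export), and pathway impact is scored by relative
   betweenness (or out-degree) centrality of matched metabolites.
5. **Regulatory impact factors** (`omicsweave.rif`) — every candidate TF
   and miRNA regulator f is scored against the DE genes j:
   `RIF1_f = mean_j PIF_j · dCo_fj²` and
   `RIF2_f = mean_j [(ē1_j r1_fj)² − (ē2_j r2_fj)²]`, where
   `PIF_j = ē_j · (ē1_j − ē2_j)` and `dCo_fj = r1(f,j) − r2(f,j)` is the
   between-condition change in Pearson co-expression; z-standardized
   across regulators.
6. **Multiple factor analysis** (`omicsweave.mfa`) — each omic table is
   centered, scaled, and divided by its first singular value; the grand
   table's PCA gives global scores, per-table partial projections, group
   contributions and per-variable correlations; co-structure between
   tables is the RV coefficient
   `trace(XXᵀYYᵀ)/√(trace((XXᵀ)²)·trace((YYᵀ)²))`.
7. **Pipeline** (`omicsweave.pipeline`, CLI `omicsweave`) — orchestrates
   all stages with a single seed, plain-text artifacts and a provenance
   manifest; reruns are bit-identical.

The synthetic generator (`omicsweave.synthetic`) produces paired cohorts
with planted differential metabolites, pathway-coupled gene blocks,
differentially co-expressed regulators and exact ground truth; see
`docs/methods.md` for the generative model.

## Worked example

```python
import omicsweave as ow

cfg = ow.SyntheticConfig(seed=1)      # 10 horses, 54 peaks, 2,000 genes, 362 miRNAs
bundle = ow.simulate(cfg)
paths = ow.write_cohort(bundle, "sim/")

config = ow.PipelineConfig(
    peaks=str(paths["peaks"]), peaks_meta=str(paths["peaks_meta"]),
    genes=str(paths["genes"]), mirnas=str(paths["mirnas"]),
    metadata=str(paths["metadata"]), pathways=str(paths["pathways"]),
    targets=str(paths["targets"]), reference=str(paths["reference"]),
    tf_list=str(paths["tfs"]), out_dir="run/", seed=7)
report = ow.run_pipeline(config)

stages = report.manifest["stages"]
print(stages["chemometrics"])
print(stages["de"])
print(stages["enrich"])
```

prints (seed 7 on the seed-1 cohort):

```
{'seed': 369571992, 'interclass_p': 0.002, 'r2': 0.99632..., 'q2': 0.77317...,
 'permutation_p': 0.000999000999000999, 'discriminant_metabolites': 13}
{'n_de_genes': 647, 'n_de_mirnas': 107}
{'n_enriched': 10, 'n_network_nodes': 270, 'n_network_edges': 461}
```

Reading: the OPLS model separates T0 from T1 with cross-validated
Q² ≈ 0.77 and beats all 1,000 label permutations (p ≈ 0.001); 647 genes and
107 miRNAs are differentially expressed at q < 0.05; 10 metabolites are
enriched in correlated metabolic DEGs, and the assembled network links
them to 246 metabolic genes and 14 miRNAs including all 5 planted
regulators. Because the cohort is synthetic, `bundle.truth` lets you
confirm the calls: here 10 of the 11 planted metabolites are recovered
with zero false positives.

The same run is available from the shell:

```bash
omicsweave simulate --out-dir sim/ --seed 1
omicsweave run --config pipeline.yaml
```

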