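# Methods

This note documents the models, default parameters and numerical choices
behind `stemsig`, and what the synthetic-data experiments do and do not
demonstrate.

## Per-cell stemness score (`stemsig.stemness`)

The score operationalises the observation that transcriptional complexity —
the number of genes detected per cell — decreases with differentiation.
Steps, for a cells × genes matrix:

1. `gene_counts`: per cell, the number of genes with expression > 0.
2. Pearson-correlate every gene's log-normalised expression with the
   gene-count vector; average the `n_top_genes` (default 200) most
   correlated genes into a gene-counts signature (GCS) per cell. Pearson is
   used here for speed on wide matrices; all *downstream* gene-level
   correlation testing is Spearman.
3. Optionally smooth the GCS over a k-nearest-neighbour cell graph
   (default `knn=30`, Euclidean in top-30-PC space) for `smoothing_iters`
   rounds of neighbour averaging (default 0).
4. Rank-normalise (average ranks for ties) and rescale to [0, 1], so the
   least stem-like cell scores 0 and the most stem-like 1.

This is a deliberately transparent variant of the published
gene-counts-based scorers: top-k correlation selection plus optional kNN
averaging replace non-negative regression and Markov diffusion. The score
is rank-based, hence invariant to monotone transformations of the GCS and
to gene/cell ordering. Scoring defaults to the malignant compartment only
(an explicit flag scores all cells), since the signature derivation is
defined on malignant cells.

Log-normalisation convention throughout: per cell (or per sample, for
bulk), scale to 10,000 total counts, then natural `log1p`.

## Signature derivation (`stemsig.signature`)

Per dataset:

* **Gx** — per-gene Spearman correlation (average-rank ties) between
  log-normalised expression and the stemness score on malignant cells;
  p-values from the t approximation `t = r·sqrt((n−2)/(1−r²))`; BH-FDR
  across all tested genes within the dataset. Pass: `r > 0` and
  `FDR < 1e-5`. Genes detected in fewer than 3 cells are skipped and
  counted. The t approximation (rather than exact permutation) is the
  standard large-n choice; at the cell numbers involved the difference is
  negligible.
* **Gy** — malignant vs all non-malignant cells; log-fold change
  `ln((mean(expm1 x_mal)+1)/(mean(expm1 x_other)+1))` on the log-normalised
  layer, two-sided Wilcoxon rank-sum (normal approximation with tie
  correction), BH-FDR within dataset. Pass: `logFC ≥ 0.25` and
  `FDR < 1e-5`. "Malignant vs all other cells" is the simplest contrast
  consistent with a binary malignancy annotation.
* **Gn** — the sorted intersection of the Gx and Gy passers; a gene absent
  from either universe fails.

Across datasets, each gene appearing in at least one Gn receives the
geometric mean of its Spearman correlations over the datasets where it
qualified (qualifying datasets only: averaging zeros over non-qualifying
datasets would annihilate every gene in a large panel). Genes with
geometric mean strictly > 0.4 (and `min_datasets` ≥ 1, exposed as a dial)
form the signature. Gx guarantees positivity of every contributing
correlation, so the geometric mean is well defined; a non-positive
contribution raises an internal-consistency error.

## Bulk scoring (`stemsig.bulk`)

The single-sample enrichment score is a documented variant of the GSVA
algorithm, not a bit-identical port. Per gene, a Gaussian-kernel
cross-sample CDF (bandwidth = per-gene SD / 4; flat genes pinned at 0.5)
converts each sample's expression into a cohort-relative statistic; per
sample, genes are ranked by that statistic and centred
(`rank − (N+1)/2`) so the sign is meaningful; a weighted KS walk over the
descending ranking steps up by `|r|^tau` (default `tau = 1`, normalised)
at member genes and down by a constant at non-members. Two score modes:
`max_dev` (signed maximum deviation, default) and `pos_minus_neg` (largest
positive plus largest negative deviation). The implementation is tested
against a naive loop re-derivation, not against any external package.
Because the core is rank-based, scores are invariant to rank-preserving
per-gene transformations; sets matching no genes score NA.

Marker abundance is a transparent marker-mean estimator: mean
`log2(x+1)` over matched markers, expecting linear-scale input.
Quadrant stratification splits on in-cohort medians (samples exactly at a
median go to the **low** side — a determinism choice), and compares any
supplied per-sample statistic between quadrants with pairwise two-sided
Wilcoxon tests, BH-adjusted; comparisons with an empty group are NA.

## Response model (`stemsig.response`)

* **Batch correction** is parametric empirical-Bayes location–scale
  adjustment (ComBat, via scanpy) with no covariates. Genes with zero
  variance inside some batch are adjusted by location only (logged).
  Note that EB shrinkage intentionally leaves a small residual of a
  planted mean offset when within-batch noise is present; a pure offset
  with no other signal is removed exactly.
* **Splitting**: validation size is `floor(n · val_fraction)`; optional
  stratification by response keeps class proportions.
* **Classifier**: kernel naive Bayes, presented statsmodels-style
  (`KernelNaiveBayes(X, y).fit() → KernelNBResults` with `summary()`,
  `predict_proba`, JSON round-trip). Priors are class frequencies with a
  Laplace pseudocount `laplace_fl` (default 0). Per feature per class, a
  1-D Gaussian KDE with Silverman bandwidth
  `0.9 · min(sd, IQR/1.34) · n^{−1/5}` scaled by `bandwidth_adjust`
  (default 0.75). The bandwidth is computed on *distinct* sample values so
  duplicated training records do not sharpen the density; degenerate
  features get a floor bandwidth of `1e-6 · (global sd + 1e-12)`.
  Prediction accumulates log densities (floored at 1e-300) plus log
  priors; a posterior of exactly 0.5 is called non-responder
  (conservative). `use_kernel=False` degenerates to Gaussian naive Bayes.
  Only this winning classifier (plus its Gaussian form) is implemented;
  a small cross-validated grid over `bandwidth_adjust` (`tune_bandwidth`)
  stands in for a full multi-algorithm bake-off.
* **ROC/AUC**: AUC via the Mann–Whitney identity (ties count ½), curve
  via threshold sweep, bootstrap 95% CI (200 resamples).
* **Survival**: Kaplan–Meier curves and the two-group log-rank test come
  from lifelines; the univariate hazard ratio is an in-repo
  Newton–Raphson fit of the Breslow partial likelihood (lifelines only
  implements Efron ties; with continuous simulated times the two
  coincide, which the tests verify). The HR is univariate by design — no
  multivariable adjustment.

## Synthetic data (`stemsig.simulate`)

All generators are pure functions of their spec (seed included).

**Single-cell panels.** Defaults per dataset: 2,000 cells × 1,500 genes,
50% malignant, 20 planted stem genes, 20 decoy-stem, 20 decoy-DE,
`gradient_strength = 1`, negative-binomial counts with fixed dispersion
0.5 (Var = μ + 0.5 μ²) — a typical droplet-data overdispersion. Every cell
carries a latent differentiation value d ~ U(0, 1); a complexity factor
`exp(gradient_strength · (d − ½))` scales all expected counts, so the
detected-gene count rises with d mechanistically rather than by post-hoc
zeroing. Planted classes: stem genes ramp `(0.1 + 2d) ×` base level in
malignant cells only (low elsewhere); decoy-stem genes ramp identically in
**all** cells (so they pass the correlation filter but fail differential
expression); decoy-DE genes are malignant-shifted but flat in d (the
converse). Because a dropout ramp inevitably feeds gene detection, every
gradient-ramped planted gene is paired with a **maturation-marker** mirror
gene ramping down in d with the same profile (truth class `maturation`),
making the planted program's net detection load symmetric in d — with
`gradient_strength = 0` the measured |Spearman| between d and gene count
is ≤ 0.05, so complexity is governed by `gradient_strength` alone. This
mirrors real differentiation, where maturation genes switch on as
stemness programs switch off.

**Bulk cohorts.** Defaults: 600 samples × 500 genes on a log-like scale
(per-gene baseline N(5, 2), residual SD 1), 50-gene planted signature
shifted by `effect_size` (default 0.8) in non-responders, responder
fraction 0.4, 3 batches with additive per-batch per-gene offsets
N(0, 0.5). Survival is exponential with baseline median 24 months,
non-responder hazard × `hazard_ratio` (default 2), administrative
censoring at 36 months — the simplest model consistent with ICI cohort
follow-up. At these defaults the 50-feature classifier is nearly
noiseless (AUC ≈ 1); the zero-effect setting provides the chance-level
control.

**CRISPR panels.** Defaults: 5,000 genes × 17 datasets; neutral genes
z ~ N(0, 1), 20 planted resistors z ~ N(−2, 1); entries missing
independently with probability 0.1. Mean-z is taken over observed entries
only (a gene observed once with z = −5 outranks a gene at mean −1 across
all datasets — the documented missing-data policy, with an optional
`min_observed` filter); top-k% counts use the floor convention; mean-z
ties break lexicographically by gene id. Inputs are assumed oriented so
negative = immune-sensitising knockout; the CLI offers per-dataset
sign flips. A robust (median/MAD) z variant is exposed alongside the
standard one.

**What passing these experiments shows — and does not.** The generators
plant clean, independent effects: no doublets or ambient RNA, a single
malignant/non-malignant dichotomy, gene-wise independent bulk noise,
ideal exponential survival, Gaussian screen noise. Recovery of planted
truth demonstrates that each operation implements its contract and that
the pipeline composes correctly; it does not certify performance on real
cohorts, where effect sizes, confounding and correlation structure are
far less favourable.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 10 seeded 3-dataset
single-cell panels at the default 2,000 × 1,500 scale for signature
recovery; 10 seeds of 900-sample bulk cohorts split 600/150/150 for the
classifier (plus 10 zero-effect seeds); 100 seeds of two ~500-sample
survival groups for HR recovery and 200 equal-hazard simulations for
log-rank calibration; 5 seeds of the default CRISPR panel; and one
22,505-gene complete panel for the top-k% set sizes. Each full run takes
about a minute on one CPU.

## Known limitations

* The stemness scorer is a simplified variant; it will not numerically
  reproduce the published packages it is inspired by.
* The enrichment scorer is likewise a documented GSVA-family variant.
* The Cox fit is univariate, two-group, Breslow ties only.
* Unit harmonisation of bulk expression (TPM vs normalised counts) is the
  caller's responsibility; matrices carry a `layer_tag` recording what
  they hold.
* Gene identifiers are opaque symbols; no alias or ortholog mapping.
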