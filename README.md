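# stemsig

Cancer stem-like cells are a recurring culprit in resistance to immune
checkpoint inhibitors (ICI): poorly differentiated tumor cells exclude
cytotoxic lymphocytes and blunt therapy response. `stemsig` implements a
complete, testable pipeline for deriving a pan-cancer **stemness gene
signature** from panels of annotated single-cell RNA-seq datasets, scoring
bulk tumors with it, predicting ICI response, and ranking candidate
therapeutic targets from CRISPR immune-screen panels. It is aimed at
computational oncologists who want each stage of such an analysis as an
auditable, unit-tested operation that runs end to end on synthetic data with
planted ground truth — no external cohort downloads required.

## The method

1. **Per-cell stemness.** For each malignant cell, the number of detectably
   expressed genes (transcriptional complexity) tracks differentiation
   status: stem-like cells express more genes. The score averages the genes
   most correlated with the per-cell gene count (optionally smoothed over a
   kNN cell graph) and rank-normalises to [0, 1].
2. **Signature derivation.** Per dataset, *Gx* = genes with Spearman *R* > 0
   and BH-FDR < 1e-5 against the stemness score; *Gy* = malignant-upregulated
   genes (two-sided Wilcoxon rank-sum, log-fold change ≥ 0.25, FDR < 1e-5);
   *Gn* = Gx ∩ Gy. Across datasets, each gene in ≥ 1 Gn gets the geometric
   mean of its correlations over qualifying datasets; genes with geometric
   mean *R* > 0.4 form the signature.
3. **Bulk scoring.** A single-sample, rank-based enrichment score in the GSVA
   family (Gaussian-kernel expression CDF + weighted Kolmogorov–Smirnov
   walk), plus marker-mean immune abundance, Spearman feature correlations,
   and median-split signature × TMB quadrant analysis (HSHT/HSLT/LSHT/LSLT).
4. **Response classification.** A kernel naive Bayes classifier
   (`fL = 0`, Silverman bandwidth × 0.75, kernel densities per
   feature per class) on batch-corrected (ComBat) expression restricted to
   the signature genes, with ROC/AUC evaluation and Kaplan–Meier / log-rank /
   Cox (Breslow) survival stratification of predicted risk groups.
5. **Target ranking.** CRISPR screen log-fold changes are z-standardised per
   dataset, averaged over observed datasets per gene, ranked ascending
   (most immune-resistant first); top-*k*% sets are tested for signature
   over-representation with a one-sided Fisher exact test.

Synthetic-data generators (`stemsig.simulate`) plant each stage's ground
truth — a latent differentiation gradient driving gene counts,
signature-to-response effects with batch structure and exponential survival,
and negative-shifted resistor genes — so discovery performance is measurable
as precision/recall against known labels.

## Worked example

```python
import numpy as np
from stemsig.simulate import (ScrnaSimSpec, BulkSimSpec, CrisprSimSpec,
    simulate_scrna_panel, simulate_bulk_cohorts, simulate_crispr_panel)
from stemsig.signature import derive_signature
from stemsig.response import (batch_correct, split_cohort, KernelNaiveBayes,
    roc_auc, km_logrank)
from stemsig.crispr import CrisprPanel, rank_genes, topk_set, enrichment_test

# 1. derive the signature from a 3-dataset synthetic single-cell panel
datasets, truth = simulate_scrna_panel([ScrnaSimSpec(seed=s) for s in (1, 2, 3)])
deriv = derive_signature(datasets)
print(f"signature: {len(deriv.signature)} genes, e.g. {deriv.signature[:4]}")

# 2. train the response classifier on a batch-corrected synthetic cohort
spec = BulkSimSpec(n_samples=900, effect_size=0.8, seed=7)
em, clin, _ = simulate_bulk_cohorts(spec)
em = batch_correct(em, clin.table["batch"])
X = em.to_frame().loc[list(spec.signature_genes)].T
y = clin.table["response_binary"].astype(bool).to_numpy()
rest, test = split_cohort(list(em.col_ids), 150 / 900, seed=8)
train, val = split_cohort(rest, 150 / 750, seed=9)
results = KernelNaiveBayes(X.loc[train], y[em.col_ids.get_indexer(train)]).fit()
auc = roc_auc(results.predict_proba(X.loc[val]), y[em.col_ids.get_indexer(val)])
print(f"validation AUC: {auc.auc:.3f}")

# 3. survival of predicted risk groups
risk = np.where(results.predict(X), "low_risk", "high_risk")
km = km_logrank(clin.table["os_time"], clin.table["os_event"], risk,
                reference="low_risk")
print(km.summary())

# 4. CRISPR target ranking
panel, ctruth = simulate_crispr_panel(CrisprSimSpec(seed=0))
ranked = rank_genes(CrisprPanel(panel))
top3 = topk_set(ranked, 3)
res = enrichment_test(ctruth["resistors"], top3, list(ranked.index))
print(f"resistors in top 3%: {len(set(ctruth['resistors']) & set(top3))}/20, "
      f"Fisher p = {res.p_value:.2e}")
```

Output:

```
signature: 20 genes, e.g. ['STEM001', 'STEM002', 'STEM003', 'STEM004']
validation AUC: 1.000
Kaplan-Meier / log-rank / proportional hazards
================================================
median OS [low_risk]: 23.55 months
median OS [high_risk]: 11.68 months
log-rank chi2 = 78.225, p = 9.19e-19
HR = 2.011 (95% CI 1.717-2.355)
resistors in top 3%: 20/20, Fisher p = 9.62e-32
```

The derived signature is exactly the 20 planted stem genes (no decoys).
The classifier separates responders cleanly at the planted effect size;
the predicted high-risk group shows roughly the doubled hazard that the
survival generator planted (HR ≈ 2); and all 20 planted immune-resistance
genes land in the top 3% of the mean-z ranking with overwhelming
over-representation.

The same stages are exposed on the command line via the `stemsig` entry
point (`simulate`, `stemness`, `derive-sig`, `score`, `train`, `predict`,
`crispr-rank`); see `stemsig --help`.

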