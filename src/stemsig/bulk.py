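"""Bulk-sample signature scoring and immune-correlate analyses.

The central operation is a single-sample, rank-based gene-set enrichment
score in the GSVA family: per gene a smooth cross-sample expression CDF
(Gaussian kernel) turns each sample's value into a cohort-relative
statistic, and a weighted Kolmogorov-Smirnov random walk over the
sample's gene ranking converts a gene set into a signed enrichment
score.  This is a documented variant of the published algorithm, not a
bit-identical reimplementation.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger("stemsig")

__all__ = [
    "gsva_like_score",
    "marker_abundance",
    "correlate_scores",
    "correlate_many",
    "quadrant_stratify",
    "group_median_correlation",
]


def _kernel_cdf_statistic(x: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel cross-sample CDF, evaluated at each sample.

    Bandwidth is the per-gene sample SD divided by 4; flat genes get a
    constant 0.5.
    """
    g, s = x.shape
    sd = x.std(axis=1, ddof=1) if s > 1 else np.zeros(g)
    out = np.empty_like(x, dtype=float)
    flat = sd <= 0
    out[flat] = 0.5
    idx = np.where(~flat)[0]
    for i in idx:
        h = sd[i] / 4.0
        out[i] = stats.norm.cdf((x[i][:, None] - x[i][None, :]) / h).mean(axis=1)
    return out


def _ks_walk(order: np.ndarray, weight: np.ndarray, member: np.ndarray, tau: float, mode: str) -> float:
    """Weighted KS running sum over genes in `order`; returns the score."""
    w = np.abs(weight[order]) ** tau
    m = member[order]
    n_out = (~m).sum()
    steps = np.where(m, w / max(w[m].sum(), np.finfo(float).tiny), -1.0 / max(n_out, 1))
    v = np.cumsum(steps)
    if mode == "max_dev":
        return float(v[np.argmax(np.abs(v))])
    if mode == "pos_minus_neg":
        return float(max(v.max(), 0.0) + min(v.min(), 0.0))
    raise ValueError(f"unknown mode {mode!r}")


def gsva_like_score(
    bulk: ExpressionMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    tau: float = 1.0,
    mode: str = "max_dev",
) -> pd.DataFrame:
    """Single-sample enrichment scores (sets x samples).

    Per sample, genes are ordered by decreasing cohort-relative rank
    statistic r = rank(kernel-CDF) - (N+1)/2; set members step the walk
    up by |r|^tau (normalised), non-members step down by a constant, and
    the score is the signed maximum deviation (``max_dev``) or the sum of
    the largest positive and negative deviations (``pos_minus_neg``).
    Sets with no genes in the matrix are scored NA with a warning.
    """
    if bulk.orientation != "genes_by_samples":
        raise ValueError("gsva_like_score expects a genes_by_samples matrix")
    n_genes, n_samples = bulk.shape
    if n_samples < 2:
        raise ValueError("the enrichment statistic needs at least 2 samples")

    x = bulk.dense().astype(float)
    cdf = _kernel_cdf_statistic(x)
    # cohort-relative rank statistic, centred so the sign is meaningful
    ranks = stats.rankdata(cdf, axis=0)
    rstat = ranks - (n_genes + 1) / 2.0

    gene_pos = {g: i for i, g in enumerate(bulk.row_ids)}
    out = pd.DataFrame(np.nan, index=list(gene_sets), columns=bulk.col_ids)
    for name, members in gene_sets.items():
        hit = np.zeros(n_genes, dtype=bool)
        matched = [gene_pos[g] for g in members if g in gene_pos]
        if not matched:
            logger.warning("gene set %r matches no genes; scored NA", name)
            continue
        hit[matched] = True
        for j in range(n_samples):
            order = np.argsort(-rstat[:, j], kind="stable")
            out.loc[name, bulk.col_ids[j]] = _ks_walk(order, rstat[:, j], hit, tau, mode)
    return out


def marker_abundance(
    bulk: ExpressionMatrix, marker_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Marker-set abundance: per sample, mean log2(x+1) over matched markers.

    A transparent marker-mean estimator of cell-population abundance;
    expects linear-scale expression.
    """
    if bulk.orientation != "genes_by_samples":
        raise ValueError("marker_abundance expects a genes_by_samples matrix")
    x = np.log2(bulk.dense().astype(float) + 1.0)
    df = pd.DataFrame(x, index=bulk.row_ids, columns=bulk.col_ids)
    out = pd.DataFrame(np.nan, index=list(marker_sets), columns=bulk.col_ids)
    for name, members in marker_sets.items():
        matched = [g for g in members if g in df.index]
        if not matched:
            logger.warning("marker set %r matches no genes; scored NA", name)
            continue
        out.loc[name] = df.loc[matched].mean(axis=0).to_numpy()
    return out


def correlate_scores(
    scores: Sequence[float], feature: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between a per-sample score and a per-sample feature."""
    s = np.asarray(scores, dtype=float)
    f = np.asarray(feature, dtype=float)
    if s.shape != f.shape:
        raise ValueError("scores and feature must align")
    keep = np.isfinite(s) & np.isfinite(f)
    if method == "spearman":
        r, p = stats.spearmanr(s[keep], f[keep])
    elif method == "pearson":
        r, p = stats.pearsonr(s[keep], f[keep])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate_many(
    scores: Sequence[float], features: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Correlate one score vector against many features, BH-corrected."""
    rows = []
    for col in features.columns:
        r, p = correlate_scores(scores, features[col].to_numpy(), method=method)
        rows.append((col, r, p))
    out = pd.DataFrame(rows, columns=["feature", "r", "p_value"]).set_index("feature")
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def group_median_correlation(
    scores: pd.Series, feature: pd.Series, groups: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Correlate per-group medians of score and feature (e.g. per cancer type)."""
    med_s = scores.groupby(groups).median()
    med_f = feature.groupby(groups).median()
    med_f = med_f.loc[med_s.index]
    return correlate_scores(med_s.to_numpy(), med_f.to_numpy(), method=method)


QUADRANTS = ("HSHT", "HSLT", "LSHT", "LSLT")


def quadrant_stratify(
    stem_scores: Sequence[float],
    tmb: Sequence[float],
    immune: Sequence[float] | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Median-split samples into signature x TMB quadrants.

    High means strictly above the in-cohort median (samples exactly at a
    median go to the low side).  When an immune statistic is supplied,
    all pairwise two-sided Wilcoxon comparisons between the four groups
    are returned, BH-adjusted; comparisons involving an empty group are
    NA.
    """
    s = np.asarray(stem_scores, dtype=float)
    t = np.asarray(tmb, dtype=float)
    if s.shape != t.shape:
        raise ValueError("stem_scores and tmb must align")
    if s.size < 4:
        raise ValueError("need at least 4 samples")
    hs = s > np.median(s)
    ht = t > np.median(t)
    labels = np.where(hs, np.where(ht, "HSHT", "HSLT"), np.where(ht, "LSHT", "LSLT"))
    labels = pd.Series(labels, name="quadrant")

    comparisons = None
    if immune is not None:
        imm = np.asarray(immune, dtype=float)
        rows = []
        for i, a in enumerate(QUADRANTS):
            for b in QUADRANTS[i + 1:]:
                xa, xb = imm[labels == a], imm[labels == b]
                if len(xa) == 0 or len(xb) == 0:
                    rows.append((a, b, len(xa), len(xb), np.nan))
                    continue
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                rows.append((a, b, len(xa), len(xb), float(p)))
        comparisons = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value"])
        ok = comparisons["p_value"].notna()
        comparisons["fdr"] = np.nan
        if ok.any():
            comparisons.loc[ok, "fdr"] = multipletests(
                comparisons.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return labels, comparisons
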