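"""Stemness signature derivation from a panel of single-cell datasets.

Per dataset: genes positively correlated with the per-cell stemness
score (Spearman R > 0, BH-FDR < 1e-5) form Gx; genes differentially
up-regulated in malignant cells (log-fold change >= 0.25, BH-FDR < 1e-5,
two-sided Wilcoxon rank-sum) form Gy; their intersection is Gn.  Across
datasets, each gene appearing in at least one Gn gets the geometric mean
of its Spearman correlations over the datasets where it qualified, and
genes with geometric mean strictly above the threshold (default 0.4)
form the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SingleCellDataset
from .stemness import StemnessResult, stemness_score

logger = logging.getLogger("stemsig")

__all__ = [
    "compute_gx",
    "compute_gy",
    "derive_gn",
    "aggregate_signature",
    "derive_signature",
    "DatasetDerivation",
    "SignatureDerivation",
]

GX_FDR = 1e-5
GY_FDR = 1e-5
GY_LOGFC = 0.25


def _spearman_vs_vector(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman correlation of x (n x p) against y (n,).

    Average ranks for ties; p-values from the t approximation
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
    """
    n = x.shape[0]
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=0) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rxc * ryc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def compute_gx(
    cells: ExpressionMatrix,
    scores: StemnessResult,
    min_cells_expressed: int = 3,
) -> pd.DataFrame:
    """Per-gene Spearman correlation with stemness on malignant cells.

    Returns a gene-indexed table with columns spearman_r, p_value, fdr,
    tested and pass_.  Genes detected in fewer than
    ``min_cells_expressed`` cells are skipped (tested=False) and the
    number skipped is logged.
    """
    if cells.orientation != "cells_by_genes":
        raise ValueError("compute_gx expects a cells_by_genes matrix")
    n_cells = cells.shape[0]
    if n_cells < 10:
        raise ValueError(f"need at least 10 cells, got {n_cells}")
    if not cells.row_ids.equals(scores.cell_ids):
        raise ValueError("cells and scores are not aligned on cell_ids")

    x = cells.lognorm().dense()
    expressed = (x > 0).sum(axis=0)
    tested = expressed >= min_cells_expressed
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("compute_gx: skipped %d genes expressed in <%d cells", n_skipped, min_cells_expressed)

    r = np.full(x.shape[1], np.nan)
    p = np.full(x.shape[1], np.nan)
    if tested.any():
        r[tested], p[tested] = _spearman_vs_vector(x[:, tested], scores.score)

    fdr = np.full(x.shape[1], np.nan)
    ok = tested & np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    passed = ok & (r > 0) & (fdr < GX_FDR)
    return pd.DataFrame(
        {
            "spearman_r": r,
            "p_value": p,
            "fdr": fdr,
            "n_expressed": expressed,
            "tested": tested,
            "pass_": passed,
        },
        index=cells.col_ids,
    )


def compute_gy(
    cells: ExpressionMatrix,
    malignant: np.ndarray,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Malignant vs non-malignant differential up-regulation per gene.

    Log-fold change on the log-normalised layer is
    ln((mean(expm1(x_mal)) + 1) / (mean(expm1(x_other)) + 1)); the test
    is a two-sided Wilcoxon rank-sum (normal approximation with tie
    correction), BH-corrected across genes.
    """
    if cells.orientation != "cells_by_genes":
        raise ValueError("compute_gy expects a cells_by_genes matrix")
    malignant = np.asarray(malignant, dtype=bool)
    if malignant.shape[0] != cells.shape[0]:
        raise ValueError("malignant flags must align with cells")
    n_mal = int(malignant.sum())
    n_oth = int((~malignant).sum())
    if n_mal == 0 or n_oth == 0:
        raise ValueError("both malignant and non-malignant cells are required")
    if min(n_mal, n_oth) < min_group_size:
        raise ValueError(f"each group needs >= {min_group_size} cells (got {n_mal}/{n_oth})")

    x = cells.lognorm().dense()
    xm, xo = x[malignant], x[~malignant]
    logfc = np.log((np.expm1(xm).mean(axis=0) + 1.0) / (np.expm1(xo).mean(axis=0) + 1.0))

    res = stats.mannwhitneyu(xm, xo, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue)
    fdr = multipletests(p, method="fdr_bh")[1]
    passed = (logfc >= GY_LOGFC) & (fdr < GY_FDR)
    return pd.DataFrame(
        {"logfc": logfc, "p_value": p, "fdr": fdr, "pass_": passed},
        index=cells.col_ids,
    )


def derive_gn(gx: pd.DataFrame, gy: pd.DataFrame) -> list[str]:
    """Sorted intersection of the Gx and Gy passers.

    A gene absent from either table's universe fails the missing filter.
    """
    gx_pass = set(gx.index[gx["pass_"]])
    gy_pass = set(gy.index[gy["pass_"]])
    return sorted(gx_pass & gy_pass)


@dataclass
class DatasetDerivation:
    """Per-dataset audit trail of the Gx/Gy/Gn filters."""

    name: str
    gx: pd.DataFrame
    gy: pd.DataFrame
    gn: list[str] = field(default_factory=list)

    def gn_correlations(self) -> pd.Series:
        return self.gx.loc[self.gn, "spearman_r"]


def aggregate_signature(
    derivations: Sequence[DatasetDerivation] | Mapping[str, pd.Series],
    threshold: float = 0.4,
    min_datasets: int = 1,
) -> pd.DataFrame:
    """Pool per-dataset Gn correlations into the final signature.

    For each gene appearing in at least one Gn, the geometric mean of its
    Spearman correlations is taken over the datasets where it qualified;
    genes with geometric mean strictly above ``threshold`` and at least
    ``min_datasets`` qualifying datasets are selected.

    Accepts either ``DatasetDerivation`` objects or a mapping
    dataset-name -> Series of per-gene correlations (the Gn members).
    """
    if len(derivations) == 0:
        raise ValueError("need at least one dataset derivation")
    if isinstance(derivations, Mapping):
        per_ds = dict(derivations)
    else:
        per_ds = {d.name: d.gn_correlations() for d in derivations}

    rows: dict[str, list[float]] = {}
    for name, r in per_ds.items():
        if (np.asarray(r.values, dtype=float) <= 0).any():
            bad = r[r <= 0].index.tolist()
            raise ValueError(
                f"dataset {name!r} contributes non-positive correlations for {bad[:5]}; "
                "Gx should guarantee positivity"
            )
        for gene, val in r.items():
            rows.setdefault(gene, []).append(float(val))

    genes = sorted(rows)
    gm = np.array([np.exp(np.mean(np.log(rows[g]))) for g in genes])
    nds = np.array([len(rows[g]) for g in genes])
    out = pd.DataFrame(
        {"geometric_mean_r": gm, "n_datasets": nds},
        index=pd.Index(genes, name="gene"),
    )
    out["selected"] = (out["geometric_mean_r"] > threshold) & (out["n_datasets"] >= min_datasets)
    return out


@dataclass
class SignatureDerivation:
    """Full derivation: per-dataset tables plus the pooled signature."""

    per_dataset: list[DatasetDerivation]
    aggregate: pd.DataFrame
    threshold: float
    min_datasets: int

    @property
    def signature(self) -> list[str]:
        return self.aggregate.index[self.aggregate["selected"]].tolist()


def derive_signature(
    datasets: Sequence[SingleCellDataset],
    threshold: float = 0.4,
    min_datasets: int = 1,
    n_top_genes: int = 200,
    smoothing_iters: int = 0,
) -> SignatureDerivation:
    """Run the whole pipeline on a panel of annotated single-cell datasets.

    Per dataset: log-normalise, score stemness on the malignant
    compartment, compute Gx there, compute Gy on all cells, intersect;
    then pool correlations across datasets into the signature.
    """
    derivs = []
    for ds in datasets:
        mal = ds.malignant_subset().lognorm()
        scores = stemness_score(mal, n_top_genes=n_top_genes, smoothing_iters=smoothing_iters)
        gx = compute_gx(mal, scores)
        gy = compute_gy(ds.matrix.lognorm(), ds.malignant)
        derivs.append(DatasetDerivation(ds.name, gx, gy, derive_gn(gx, gy)))
    agg = aggregate_signature(derivs, threshold=threshold, min_datasets=min_datasets)
    return SignatureDerivation(derivs, agg, threshold, min_datasets)
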