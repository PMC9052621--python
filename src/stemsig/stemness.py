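"""Per-cell stemness scoring from transcriptional complexity.

The scorer exploits the empirical association between the number of
detectably expressed genes in a cell and its differentiation status:
less differentiated (more stem-like) cells express more genes.  The
score is built in three steps: (1) count expressed genes per cell,
(2) average the expression of the genes most correlated with that count
(the gene-counts signature, GCS), optionally smoothing over a
k-nearest-neighbour cell graph, and (3) rank-normalise to [0, 1], higher
meaning more stem-like.

This is a deliberately transparent variant of the published
gene-counts-based scorers: top-k correlation selection plus optional kNN
averaging stand in for non-negative regression and Markov diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .containers import ExpressionMatrix

logger = logging.getLogger("stemsig")

__all__ = ["StemnessResult", "gene_counts", "stemness_score"]


@dataclass
class StemnessResult:
    cell_ids: pd.Index
    gene_counts: np.ndarray  # detected genes per cell
    gcs: np.ndarray  # gene-counts-signature value per cell
    score: np.ndarray  # stemness in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_counts": self.gene_counts, "gcs": self.gcs, "score": self.score},
            index=self.cell_ids,
        )


def gene_counts(cells: ExpressionMatrix) -> np.ndarray:
    """Number of genes with expression > 0 per cell (row)."""
    if cells.orientation != "cells_by_genes":
        raise ValueError("gene_counts expects a cells_by_genes matrix")
    if cells.shape[0] == 0 or cells.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if sp.issparse(cells.values):
        return np.asarray((cells.values > 0).sum(axis=1)).ravel()
    return (cells.dense() > 0).sum(axis=1)


def _minmax_rank(x: np.ndarray) -> np.ndarray:
    r = rankdata(x)  # average ranks for ties
    lo, hi = r.min(), r.max()
    if hi == lo:
        return np.full_like(r, 0.5, dtype=float)
    return (r - lo) / (hi - lo)


def stemness_score(
    cells: ExpressionMatrix,
    n_top_genes: int = 200,
    knn: int = 30,
    smoothing_iters: int = 0,
    n_pcs: int = 30,
) -> StemnessResult:
    """Score each cell's stemness in [0, 1] from its expression profile.

    Parameters
    ----------
    cells
        cells x genes matrix; raw counts are log-normalised internally.
    n_top_genes
        Number of genes (by Pearson correlation with the per-cell gene
        count) averaged into the gene-counts signature.
    knn, smoothing_iters
        If ``smoothing_iters`` > 0 the signature is averaged over each
        cell's ``knn`` nearest neighbours (Euclidean in top-PC space)
        that many times before ranking.
    """
    if cells.orientation != "cells_by_genes":
        raise ValueError("stemness_score expects a cells_by_genes matrix")
    n_cells, n_genes = cells.shape
    if n_cells < 10:
        raise ValueError(f"need at least 10 cells, got {n_cells}")
    if smoothing_iters > 0 and knn >= n_cells:
        raise ValueError("knn must be smaller than the number of cells")
    if n_top_genes > n_genes:
        logger.warning("n_top_genes=%d > %d genes; clamping", n_top_genes, n_genes)
        n_top_genes = n_genes

    counts = gene_counts(cells)
    x = cells.lognorm().dense()

    # Pearson correlation of every gene with the gene-count vector
    xc = x - x.mean(axis=0)
    cc = counts - counts.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc * cc[:, None]).sum(axis=0) / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)  # flat genes never selected

    top = np.argsort(-corr, kind="stable")[:n_top_genes]
    gcs = x[:, top].mean(axis=1)

    if smoothing_iters > 0:
        from sklearn.decomposition import PCA
        from sklearn.neighbors import NearestNeighbors

        k = min(n_pcs, n_cells - 1, n_genes)
        pcs = PCA(n_components=k, random_state=0).fit_transform(x)
        nn = NearestNeighbors(n_neighbors=knn + 1).fit(pcs)
        _, idx = nn.kneighbors(pcs)  # includes self at position 0
        for _ in range(smoothing_iters):
            gcs = gcs[idx].mean(axis=1)

    score = _minmax_rank(gcs)
    return StemnessResult(cells.row_ids, counts, gcs, score)
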