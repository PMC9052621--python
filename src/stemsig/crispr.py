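"""CRISPR screen aggregation: z-score panels, mean-z ranking, top-k%
immune-resistance sets and over-representation of a signature among them.

Input panels are gene x dataset matrices of standardised log-fold
changes, oriented so that negative values mark knockouts that sensitise
tumors to immune killing; missing entries (a gene not covered by a
screen) are NaN and are simply skipped when averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("stemsig")

__all__ = [
    "lfc_from_counts",
    "zscore_normalize",
    "CrisprPanel",
    "rank_genes",
    "topk_set",
    "enrichment_test",
    "EnrichmentResult",
]


def lfc_from_counts(
    treat_counts: pd.Series,
    ctrl_counts: pd.Series,
    pseudocount: float = 1.0,
    gene_map: pd.Series | None = None,
) -> pd.Series:
    """Per-gene log2 fold change of guide abundance, treated vs control.

    Counts are scaled to library proportions; a pseudo-proportion
    pseudocount/library_size stabilises zeros.  When ``gene_map`` maps
    sgRNA ids to genes, guide-level values are averaged per gene.
    """
    if not treat_counts.index.equals(ctrl_counts.index):
        raise ValueError("treat and ctrl must share the same index")
    t = treat_counts.to_numpy(dtype=float)
    c = ctrl_counts.to_numpy(dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("counts must be non-negative")
    tt, ct = t.sum(), c.sum()
    if tt == 0 or ct == 0:
        raise ValueError("zero total reads in a library")
    lfc = pd.Series(
        np.log2((t / tt + pseudocount / tt) / (c / ct + pseudocount / ct)),
        index=treat_counts.index,
        name="lfc",
    )
    if gene_map is not None:
        lfc = lfc.groupby(gene_map.reindex(lfc.index)).mean()
        lfc.index.name = "gene"
    return lfc


def zscore_normalize(lfc: pd.Series, robust: bool = False) -> pd.Series:
    """Standardise a dataset's log-fold changes over observed genes.

    Default: (x - mean) / sd (ddof=1).  ``robust=True`` uses
    (x - median) / (1.4826 * MAD) instead.  A constant column is an
    error.  Missing entries stay missing.
    """
    x = lfc.to_numpy(dtype=float)
    obs = np.isfinite(x)
    v = x[obs]
    if len(v) < 2:
        raise ValueError("need at least 2 observed values")
    if robust:
        center = np.median(v)
        scale = 1.4826 * np.median(np.abs(v - center))
    else:
        center = v.mean()
        scale = v.std(ddof=1)
    if scale == 0:
        raise ValueError("constant column: zero spread")
    out = np.full_like(x, np.nan)
    out[obs] = (v - center) / scale
    return pd.Series(out, index=lfc.index, name=lfc.name)


@dataclass
class CrisprPanel:
    """Gene x dataset z-score matrix; NaN marks missing entries."""

    z: pd.DataFrame

    def __post_init__(self) -> None:
        if self.z.index.has_duplicates:
            raise ValueError("duplicate gene ids in panel")
        if self.z.columns.has_duplicates:
            raise ValueError("duplicate dataset ids in panel")

    @property
    def mask(self) -> pd.DataFrame:
        """True where an entry is missing."""
        return self.z.isna()

    @property
    def mean_z(self) -> pd.Series:
        """Mean z over observed datasets; NaN for fully missing genes."""
        return self.z.mean(axis=1, skipna=True)


def rank_genes(panel: CrisprPanel, min_observed: int = 1) -> pd.DataFrame:
    """Rank genes ascending by mean z over observed entries.

    Rank 1 = most immune-resistant (lowest mean z).  Genes observed in
    fewer than ``min_observed`` datasets are dropped; ties are broken by
    gene id lexicographically for reproducibility.
    """
    n_obs = panel.z.notna().sum(axis=1)
    mean_z = panel.mean_z[n_obs >= min_observed]
    if mean_z.empty:
        raise ValueError("no genes with enough observed entries")
    out = pd.DataFrame({"mean_z": mean_z, "n_observed": n_obs[mean_z.index]})
    # deterministic: sort by (mean_z, gene id)
    out = out.assign(_gene=out.index.astype(str)).sort_values(["mean_z", "_gene"]).drop(columns="_gene")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def topk_set(ranked: pd.DataFrame, pct: float) -> list[str]:
    """The floor(n * pct / 100) top-ranked genes (most immune-resistant)."""
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    k = int(np.floor(len(ranked) * pct / 100.0))
    return ranked.index[:k].tolist()


@dataclass
class EnrichmentResult:
    overlap: list[str]
    table: tuple[int, int, int, int]  # a, b, c, d of the 2x2 table
    odds_ratio: float
    p_value: float


def enrichment_test(
    signature: Sequence[str],
    topk: Sequence[str],
    universe: Sequence[str],
) -> EnrichmentResult:
    """One-sided Fisher's exact test for over-representation of the
    signature among the top-ranked genes.

    The signature is intersected with the universe first (genes outside
    the screened universe are dropped and the count logged); the overlap
    is returned in top-list order (i.e. by rank).
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    sig_all = list(dict.fromkeys(signature))
    sig = [g for g in sig_all if g in uni_set]
    dropped = len(sig_all) - len(sig)
    if dropped:
        logger.info("enrichment_test: dropped %d signature genes outside the universe", dropped)
    top = [g for g in dict.fromkeys(topk) if g in uni_set]
    sig_set, top_set = set(sig), set(top)

    overlap = [g for g in top if g in sig_set]  # ordered by rank
    a = len(overlap)
    b = len(sig_set) - a
    c = len(top_set) - a
    d = len(uni_set) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(overlap, (a, b, c, d), float(odds), float(p))
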