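"""In-memory containers shared across the pipeline.

Bulk expression matrices are oriented genes x samples; single-cell
matrices cells x genes.  The orientation is recorded explicitly on the
container rather than guessed from shape, and every operation states
which orientation it expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYER_TAGS = ("raw_counts", "lognorm", "tpm_like")
ORIENTATIONS = ("genes_by_samples", "cells_by_genes")


def _as_index(ids: Sequence[str], what: str) -> pd.Index:
    idx = pd.Index(np.asarray(ids, dtype=object))
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return idx


@dataclass
class ExpressionMatrix:
    """A labelled expression matrix with an explicit orientation and layer.

    Parameters
    ----------
    values
        2-D numeric array or scipy sparse matrix.
    row_ids, col_ids
        Gene/cell/sample identifiers for rows and columns; must be unique.
    orientation
        ``genes_by_samples`` (bulk) or ``cells_by_genes`` (single-cell).
    layer_tag
        ``raw_counts`` (non-negative), ``lognorm`` (log1p of a per-cell
        10k-scaled profile) or ``tpm_like``.
    """

    values: np.ndarray | sp.spmatrix
    row_ids: pd.Index
    col_ids: pd.Index
    orientation: str = "genes_by_samples"
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.row_ids = _as_index(self.row_ids, "row_ids")
        self.col_ids = _as_index(self.col_ids, "col_ids")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        dense_sample = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense_sample)):
            raise ValueError("expression values must be finite")
        if self.layer_tag == "raw_counts" and dense_sample.size and dense_sample.min() < 0:
            raise ValueError("raw_counts layer must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.row_ids, columns=self.col_ids)

    # -- orientation helpers -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.row_ids if self.orientation == "genes_by_samples" else self.col_ids

    def transpose(self) -> "ExpressionMatrix":
        other = (
            "cells_by_genes"
            if self.orientation == "genes_by_samples"
            else "genes_by_samples"
        )
        return ExpressionMatrix(
            self.values.T, self.col_ids, self.row_ids, other, self.layer_tag
        )

    def subset_rows(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = self.row_ids.get_indexer(pd.Index(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"row ids not found: {missing[:5]}")
        vals = self.values[pos, :] if not sp.issparse(self.values) else self.values.tocsr()[pos, :]
        return ExpressionMatrix(vals, self.row_ids[pos], self.col_ids, self.orientation, self.layer_tag)

    def lognorm(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Per-profile scaling to `scale` counts followed by natural log1p.

        Profiles are cells (rows) for cells_by_genes, samples (columns)
        for genes_by_samples.  Raw counts only; lognorm input is returned
        unchanged.
        """
        if self.layer_tag == "lognorm":
            return self
        x = self.dense().astype(float)
        axis = 1 if self.orientation == "cells_by_genes" else 0
        totals = x.sum(axis=axis, keepdims=True)
        totals[totals == 0] = 1.0
        out = np.log1p(x / totals * scale)
        return ExpressionMatrix(out, self.row_ids, self.col_ids, self.orientation, "lognorm")


RESPONDER_MAP = {"CR": True, "PR": True, "SD": False, "PD": False}


def derive_response_binary(response_raw: pd.Series) -> pd.Series:
    """Responder iff best overall response is CR or PR; SD/PD are
    non-responders; anything else (incl. NA) stays NA."""
    raw = response_raw.astype("string").str.strip().str.upper()
    out = raw.map({k: v for k, v in RESPONDER_MAP.items()})
    return out.astype("boolean")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations for an immunotherapy cohort.

    Carries RECIST best overall response (raw and binarised), overall
    survival in months with an event indicator, tumor mutational burden
    and a batch/cohort label.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id",)
    OPTIONAL = ("response_raw", "os_time", "os_event", "tmb", "batch")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id: {dupes[:5]}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        df["response_binary"] = derive_response_binary(df["response_raw"])
        os_time = pd.to_numeric(df["os_time"], errors="coerce")
        if (os_time.dropna() < 0).any():
            raise ValueError("os_time must be non-negative")
        df["os_time"] = os_time
        df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
        df["tmb"] = pd.to_numeric(df["tmb"], errors="coerce")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(df)


@dataclass
class SingleCellDataset:
    """A single-cell expression dataset with malignant/non-malignant calls.

    The unit of signature derivation: stemness is scored on the malignant
    compartment, differential expression contrasts malignant against all
    other cells.
    """

    matrix: ExpressionMatrix  # cells x genes
    malignant: np.ndarray  # bool per cell
    name: str = "dataset"
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.matrix.orientation != "cells_by_genes":
            raise ValueError("SingleCellDataset expects a cells_by_genes matrix")
        self.malignant = np.asarray(self.malignant, dtype=bool)
        if self.malignant.shape[0] != self.matrix.shape[0]:
            raise ValueError("malignant flags must align with cells (rows)")

    @property
    def cell_ids(self) -> pd.Index:
        return self.matrix.row_ids

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.col_ids

    def malignant_subset(self) -> ExpressionMatrix:
        keep = self.matrix.row_ids[self.malignant]
        return self.matrix.subset_rows(keep)
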