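"""Readers and writers for the on-disk formats the pipeline touches.

MatrixMarket triplets with gene/barcode sidecars, dense TSV matrices,
GMT gene sets, clinical TSVs and YAML configs.  No science lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger("stemsig")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a terse format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _read_ids(path: str | Path) -> list[str]:
    with open(path) as fh:
        # first whitespace-separated token per line (10x sidecars may carry
        # a second annotation column)
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def dedupe_ids(ids: Sequence[str], what: str = "gene") -> list[str]:
    """Disambiguate duplicate symbols by suffixing .1, .2, ...; logged."""
    seen: dict[str, int] = {}
    out = []
    n_dupes = 0
    for s in ids:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
            n_dupes += 1
        else:
            seen[s] = 0
            out.append(s)
    if n_dupes:
        logger.warning("deduplicated %d duplicate %s symbols by suffixing", n_dupes, what)
    return out


def read_mtx_triplet(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Load a MatrixMarket genes x cells matrix with sidecar identifiers.

    Returns a cells_by_genes ``ExpressionMatrix`` (rows = barcodes),
    sparse-preserving.  Duplicate gene symbols are suffixed ``.1``, ``.2``.
    """
    m = scipy.io.mmread(str(matrix_path))
    genes = _read_ids(genes_path)
    barcodes = _read_ids(barcodes_path)
    if m.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: {matrix_path} declares {m.shape} but "
            f"{genes_path} has {len(genes)} genes and "
            f"{barcodes_path} has {len(barcodes)} barcodes"
        )
    genes = dedupe_ids(genes, "gene")
    barcodes = dedupe_ids(barcodes, "barcode")
    return ExpressionMatrix(
        sp.csr_matrix(m.T),
        pd.Index(barcodes),
        pd.Index(genes),
        orientation="cells_by_genes",
        layer_tag="raw_counts",
    )


def write_mtx_triplet(
    em: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a cells_by_genes matrix as genes x cells MatrixMarket + sidecars."""
    if em.orientation != "cells_by_genes":
        raise ValueError("write_mtx_triplet expects a cells_by_genes matrix")
    vals = em.values if sp.issparse(em.values) else sp.csr_matrix(em.values)
    scipy.io.mmwrite(str(matrix_path), vals.T)
    Path(genes_path).write_text("\n".join(em.col_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(em.row_ids) + "\n")


# -- GMT gene sets -----------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered name -> member-list mapping.

    Member order is preserved; within-set duplicates are dropped with a
    warning.  A line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning(
                    "gene set %r: removed %d duplicate members", name, len(members) - len(uniq)
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = uniq
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# -- dense matrices ----------------------------------------------------------

def read_dense_matrix(
    path: str | Path,
    orientation: str = "genes_by_samples",
    layer_tag: str = "tpm_like",
) -> ExpressionMatrix:
    """Read a dense TSV/CSV matrix with row identifiers in the first column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        pd.Index(df.index.astype(str)),
        pd.Index(df.columns.astype(str)),
        orientation=orientation,
        layer_tag=layer_tag,
    )


def write_dense_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    em.to_frame().to_csv(path, sep=sep)


# -- clinical tables ---------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; the responder flag is derived from response_raw.

    Missing optional columns are filled with NA (logged); duplicate
    sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ClinicalTable.OPTIONAL if c not in df.columns]
    if missing:
        logger.info("clinical table %s: filling absent columns with NA: %s", path, missing)
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index=False)


# -- config ------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
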