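"""Synthetic data generators with planted ground truth.

Three generators emulate the three input families the pipeline consumes:

* multi-dataset single-cell panels in which a latent differentiation
  gradient drives transcriptional complexity (number of detected genes)
  and a planted set of malignant-specific, stemness-correlated genes;
* multi-cohort bulk immunotherapy data with batch effects, a
  signature-to-response effect and exponential survival;
* multi-dataset CRISPR screen z-score panels with planted
  immune-resistance genes and missing entries.

All generators are pure functions of their spec (the seed is part of the
spec), so equal specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, SingleCellDataset

__all__ = [
    "ScrnaSimSpec",
    "BulkSimSpec",
    "CrisprSimSpec",
    "simulate_scrna",
    "simulate_scrna_panel",
    "simulate_bulk_cohorts",
    "simulate_crispr_panel",
]


# ---------------------------------------------------------------------------
# single-cell panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrnaSimSpec:
    """Conditions for one simulated single-cell dataset.

    ``n_stem_genes`` are malignant-specific AND stemness-correlated (the
    genes the derivation is supposed to find); ``n_decoy_stem_genes``
    track the differentiation gradient in every cell (not
    malignant-specific, so they must fail the differential-expression
    filter); ``n_decoy_de_genes`` are malignant-upregulated but flat in
    the gradient (so they must fail the stemness-correlation filter).
    ``gradient_strength`` scales how strongly a cell's position on the
    latent differentiation axis d in [0, 1] inflates its expected library
    complexity.
    """

    n_cells: int = 2000
    n_genes: int = 1500
    malignant_fraction: float = 0.5
    n_stem_genes: int = 20
    n_decoy_stem_genes: int = 20
    n_decoy_de_genes: int = 20
    gradient_strength: float = 1.0
    dispersion: float = 0.5
    stem_gene_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.malignant_fraction <= 1):
            raise ValueError("malignant_fraction must be in (0, 1]")
        for f in ("n_cells", "n_genes", "n_stem_genes", "n_decoy_stem_genes", "n_decoy_de_genes"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        n_planted = (
            self.n_stem_genes + self.n_decoy_stem_genes + self.n_decoy_de_genes
            # maturation mirrors of every gradient-ramped planted gene
            + self.n_stem_genes + self.n_decoy_stem_genes
        )
        if n_planted > self.n_genes:
            raise ValueError("planted genes (incl. maturation mirrors) exceed the gene universe")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nbinom(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def gene_names(spec: ScrnaSimSpec) -> tuple[list[str], pd.DataFrame]:
    """Fixed gene naming shared across panel datasets, plus the truth table."""
    names, classes = [], []
    for i in range(spec.n_stem_genes):
        names.append(f"STEM{i + 1:03d}")
        classes.append("stem")
    for i in range(spec.n_decoy_stem_genes):
        names.append(f"DSTEM{i + 1:03d}")
        classes.append("decoy_stem")
    for i in range(spec.n_decoy_de_genes):
        names.append(f"DDE{i + 1:03d}")
        classes.append("decoy_de")
    for i in range(spec.n_stem_genes + spec.n_decoy_stem_genes):
        names.append(f"MAT{i + 1:03d}")
        classes.append("maturation")
    n_bg = spec.n_genes - len(names)
    for i in range(n_bg):
        names.append(f"G{i + 1:05d}")
        classes.append("background")
    truth = pd.DataFrame({"gene": names, "gene_class": classes})
    return names, truth


def simulate_scrna(spec: ScrnaSimSpec, name: str = "sim") -> tuple[SingleCellDataset, dict]:
    """Simulate one dataset; returns the dataset and its truth tables.

    Mechanism: every cell has a latent differentiation value d ~ U(0, 1)
    and a complexity factor exp(gradient_strength * (d - 1/2)) that
    scales all of its expected gene counts, so the number of detected
    genes rises with d mechanistically rather than by post-hoc zeroing.
    Stem genes ramp with d in malignant cells only; decoy_stem genes ramp
    with d in all cells; decoy_de genes are malignant-shifted but flat.
    Every gradient-ramped planted gene is paired with a maturation-marker
    mirror gene that ramps down in d with the same profile, so the net
    detection load of the planted program is symmetric in d and the
    complexity gradient is governed by gradient_strength alone.
    """
    rng = np.random.default_rng(spec.seed)
    n_mal = int(round(spec.n_cells * spec.malignant_fraction))
    if n_mal == 0:
        raise ValueError("malignant_fraction too small: no malignant cells")

    malignant = np.zeros(spec.n_cells, dtype=bool)
    malignant[rng.choice(spec.n_cells, size=n_mal, replace=False)] = True
    d = rng.uniform(size=spec.n_cells)
    complexity = np.exp(spec.gradient_strength * (d - 0.5))

    names, truth_genes = gene_names(spec)
    cls = truth_genes["gene_class"].to_numpy()
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=spec.n_genes)

    # cell x gene expected counts
    mu = np.outer(np.ones(spec.n_cells), base)
    ramp = 0.1 + 2.0 * d  # expression ramp along the differentiation axis
    anti = 0.1 + 2.0 * (1.0 - d)  # mirrored ramp for maturation markers
    is_stem = cls == "stem"
    is_dstem = cls == "decoy_stem"
    is_dde = cls == "decoy_de"
    is_mat = cls == "maturation"
    n_mat_mal = spec.n_stem_genes  # mirrors of the malignant-only stem ramp
    mat_idx = np.where(is_mat)[0]
    mu[:, is_stem] = spec.stem_gene_mean * 0.1
    mu[np.ix_(malignant, np.where(is_stem)[0])] = spec.stem_gene_mean * ramp[malignant, None]
    mu[:, is_dstem] = spec.stem_gene_mean * ramp[:, None]
    mu[:, is_dde] = spec.stem_gene_mean * 0.1
    mu[np.ix_(malignant, np.where(is_dde)[0])] = spec.stem_gene_mean
    mu[:, mat_idx[:n_mat_mal]] = spec.stem_gene_mean * 0.1
    mu[np.ix_(malignant, mat_idx[:n_mat_mal])] = spec.stem_gene_mean * anti[malignant, None]
    mu[:, mat_idx[n_mat_mal:]] = spec.stem_gene_mean * anti[:, None]
    mu *= complexity[:, None]

    counts = _nbinom(rng, mu, spec.dispersion)
    cells = [f"{name}_cell{i + 1:05d}" for i in range(spec.n_cells)]
    em = ExpressionMatrix(
        counts.astype(np.int64),
        pd.Index(cells),
        pd.Index(names),
        orientation="cells_by_genes",
        layer_tag="raw_counts",
    )
    ds = SingleCellDataset(em, malignant, name=name)
    truth = {
        "gene_classes": truth_genes,
        "latent_d": pd.Series(d, index=cells, name="latent_d"),
        "malignant": pd.Series(malignant, index=cells, name="malignant"),
    }
    return ds, truth


def simulate_scrna_panel(
    specs: Sequence[ScrnaSimSpec],
) -> tuple[list[SingleCellDataset], dict]:
    """Simulate a multi-dataset panel sharing one gene universe.

    All specs must agree on the planted-gene layout so that gene names
    coincide across datasets (the aggregation step intersects by name).
    """
    if len(specs) == 0:
        raise ValueError("need at least one spec")
    layout = [(s.n_genes, s.n_stem_genes, s.n_decoy_stem_genes, s.n_decoy_de_genes) for s in specs]
    if len(set(layout)) != 1:
        raise ValueError("panel specs must share the same gene layout")
    datasets, per_ds_truth = [], {}
    for i, spec in enumerate(specs):
        ds, truth = simulate_scrna(spec, name=f"ds{i + 1}")
        datasets.append(ds)
        per_ds_truth[ds.name] = truth
    panel_truth = {
        "gene_classes": per_ds_truth[datasets[0].name]["gene_classes"],
        "per_dataset": per_ds_truth,
    }
    return datasets, panel_truth


# ---------------------------------------------------------------------------
# bulk immunotherapy cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkSimSpec:
    """Conditions for a combined multi-cohort bulk expression study.

    ``effect_size`` is the mean log-scale shift of signature genes in
    non-responders; ``batch_sd`` the standard deviation of additive
    per-batch per-gene offsets; survival is exponential with the
    non-responder (high-risk) hazard multiplied by ``hazard_ratio`` and
    administrative censoring at ``censor_horizon`` months.
    """

    n_samples: int = 600
    n_genes: int = 500
    signature_genes: tuple[str, ...] = tuple(f"SIG{i + 1:03d}" for i in range(50))
    effect_size: float = 0.8
    responder_fraction: float = 0.4
    n_batches: int = 3
    batch_sd: float = 0.5
    hazard_ratio: float = 2.0
    baseline_median_os: float = 24.0
    censor_horizon: float = 36.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.responder_fraction < 1):
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if len(self.signature_genes) == 0:
            raise ValueError("signature_genes must be non-empty")
        if len(self.signature_genes) > self.n_genes:
            raise ValueError("signature larger than gene universe")


def simulate_bulk_cohorts(spec: BulkSimSpec) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Simulate a combined bulk cohort with clinical annotations.

    Returns (expression genes x samples on a log-like scale, clinical
    table, truth dict with the per-sample responder labels and batch
    assignment).
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.signature_genes) + [
        f"B{i + 1:05d}" for i in range(spec.n_genes - len(spec.signature_genes))
    ]
    samples = [f"s{i + 1:04d}" for i in range(spec.n_samples)]

    responder = rng.uniform(size=spec.n_samples) < spec.responder_fraction
    batch = rng.integers(0, spec.n_batches, size=spec.n_samples)
    base = rng.normal(5.0, 2.0, size=spec.n_genes)

    x = base[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    n_sig = len(spec.signature_genes)
    x[:n_sig, :][:, ~responder] += spec.effect_size
    batch_offsets = rng.normal(0.0, spec.batch_sd, size=(spec.n_genes, spec.n_batches))
    x += batch_offsets[:, batch]

    em = ExpressionMatrix(
        x, pd.Index(genes), pd.Index(samples), orientation="genes_by_samples", layer_tag="tpm_like"
    )

    # survival: exponential, high-risk (non-responder) hazard scaled up
    lam0 = np.log(2.0) / spec.baseline_median_os
    lam = np.where(responder, lam0, lam0 * spec.hazard_ratio)
    t = rng.exponential(1.0 / lam)
    event = (t <= spec.censor_horizon).astype(int)
    os_time = np.minimum(t, spec.censor_horizon)

    response_raw = np.where(
        responder,
        rng.choice(["CR", "PR"], size=spec.n_samples),
        rng.choice(["SD", "PD"], size=spec.n_samples),
    )
    tmb = np.round(rng.lognormal(mean=2.0, sigma=1.0, size=spec.n_samples), 1)
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "response_raw": response_raw,
                "os_time": np.round(os_time, 4),
                "os_event": event,
                "tmb": tmb,
                "batch": [f"cohort{b + 1}" for b in batch],
            }
        )
    )
    truth = {
        "responder": pd.Series(responder, index=samples),
        "high_risk": pd.Series(~responder, index=samples),
        "batch": pd.Series(batch, index=samples),
    }
    return em, clin, truth


# ---------------------------------------------------------------------------
# CRISPR screen panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrisprSimSpec:
    """Conditions for a simulated multi-dataset CRISPR z-score panel.

    Neutral genes draw z ~ N(0, 1) per dataset; planted resistor genes
    draw z ~ N(resistor_effect, 1) with resistor_effect < 0 (knockout
    sensitizes the tumor to immune killing).  Entries go missing
    independently with probability ``missing_fraction``.
    """

    n_genes: int = 5000
    n_datasets: int = 17
    n_resistors: int = 20
    resistor_effect: float = -2.0
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_resistors > self.n_genes:
            raise ValueError("more resistors than genes")
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")


def simulate_crispr_panel(spec: CrisprSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a gene x dataset z-score panel with NaN for missing entries."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"R{i + 1:03d}" for i in range(spec.n_resistors)] + [
        f"N{i + 1:05d}" for i in range(spec.n_genes - spec.n_resistors)
    ]
    z = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_datasets))
    z[: spec.n_resistors, :] += spec.resistor_effect
    if spec.missing_fraction > 0:
        mask = rng.uniform(size=z.shape) < spec.missing_fraction
        z[mask] = np.nan
    panel = pd.DataFrame(
        z, index=pd.Index(genes, name="gene"),
        columns=[f"crispr{j + 1:02d}" for j in range(spec.n_datasets)],
    )
    truth = {"resistors": genes[: spec.n_resistors]}
    return panel, truth
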