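"""Immunotherapy response classification and survival stratification.

The classifier is a kernel naive Bayes: class priors times a product of
per-feature one-dimensional Gaussian kernel densities (bandwidth by
Silverman's rule scaled by ``bandwidth_adjust``, default 0.75, with
Laplace smoothing ``laplace_fl``, default 0).  ``use_kernel=False``
degenerates to Gaussian naive Bayes.  The module also carries the
standard machinery around the classifier: empirical-Bayes batch
correction, train/validation splitting, ROC/AUC, and Kaplan-Meier /
log-rank / proportional-hazards survival comparison of the predicted
risk groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger("stemsig")

__all__ = [
    "batch_correct",
    "split_cohort",
    "KernelNaiveBayes",
    "KernelNBResults",
    "train_nb",
    "predict_response",
    "roc_auc",
    "RocResult",
    "km_logrank",
    "KmResult",
    "tune_bandwidth",
]

_DENSITY_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def batch_correct(
    bulk: ExpressionMatrix, batch: Sequence[str], allow_single: bool = False
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects from a bulk matrix.

    Location-scale adjustment with empirical-Bayes shrinkage of per-batch
    per-gene means and variances toward cohort-level priors (parametric
    ComBat, no covariates).  Genes with zero variance inside some batch
    are adjusted by location only and logged.
    """
    if bulk.orientation != "genes_by_samples":
        raise ValueError("batch_correct expects a genes_by_samples matrix")
    batch = pd.Series(list(batch), index=bulk.col_ids, name="batch").astype(str)
    levels = batch.unique()
    if len(levels) < 2:
        if allow_single:
            return bulk
        raise ValueError("need >= 2 batches (or pass allow_single=True)")
    counts = batch.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"every batch needs >= 3 samples; too small: {small}")

    x = bulk.dense().astype(float)
    # genes degenerate within some batch: location-only adjustment
    degenerate = np.zeros(x.shape[0], dtype=bool)
    for lev in levels:
        cols = (batch == lev).to_numpy()
        degenerate |= x[:, cols].std(axis=1, ddof=1) == 0
    out = x.copy()
    if degenerate.any():
        logger.info("batch_correct: %d genes adjusted by location only", int(degenerate.sum()))
        grand = x[degenerate].mean(axis=1, keepdims=True)
        for lev in levels:
            cols = (batch == lev).to_numpy()
            bmean = x[np.ix_(degenerate, cols)].mean(axis=1, keepdims=True)
            out[np.ix_(degenerate, cols)] = x[np.ix_(degenerate, cols)] - bmean + grand

    ok = ~degenerate
    if ok.any():
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(
            X=x[ok].T.copy(),
            obs=pd.DataFrame({"batch": batch.to_numpy()}, index=list(bulk.col_ids)),
        )
        sc.pp.combat(adata, key="batch")
        out[ok] = np.asarray(adata.X).T
    return ExpressionMatrix(out, bulk.row_ids, bulk.col_ids, bulk.orientation, bulk.layer_tag)


def split_cohort(
    sample_ids: Sequence[str],
    val_fraction: float = 0.2,
    seed: int = 0,
    stratify: Optional[Sequence] = None,
) -> tuple[list[str], list[str]]:
    """Random train/validation partition with floor(n * val_fraction)
    validation samples; optionally stratified by a label."""
    ids = list(sample_ids)
    n = len(ids)
    n_val = int(np.floor(n * val_fraction))
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        val_idx = set(perm[:n_val].tolist())
    else:
        strat = pd.Series(list(stratify))
        val_idx = set()
        order = []
        for _, grp in strat.groupby(strat, dropna=False):
            gi = rng.permutation(grp.index.to_numpy())
            k = int(np.floor(len(gi) * val_fraction))
            val_idx.update(gi[:k].tolist())
            order.extend(gi[k:].tolist())
        # top up to the exact floor count from the leftover pool
        extra = rng.permutation(np.array(order))
        for i in extra:
            if len(val_idx) >= n_val:
                break
            val_idx.add(int(i))
    train = [ids[i] for i in range(n) if i not in val_idx]
    val = [ids[i] for i in range(n) if i in val_idx]
    return train, val


# ---------------------------------------------------------------------------
# kernel naive Bayes
# ---------------------------------------------------------------------------

def _silverman(x: np.ndarray) -> float:
    # computed on distinct values so duplicated training records do not
    # artificially sharpen the density
    u = np.unique(x)
    n = len(u)
    sd = u.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(u, [75, 25]))
    spread = min(sd, iqr / 1.34) if min(sd, iqr / 1.34) > 0 else max(sd, iqr / 1.34)
    return 0.9 * spread * n ** (-0.2)


@dataclass
class KernelNBResults:
    """Fitted kernel naive Bayes classifier.

    ``class_order`` is (non-responder, responder); ``priors`` follow that
    order.  Per feature per class, either kernel training points + one
    bandwidth, or a (mean, sd) pair for the Gaussian degenerate form.
    """

    feature_names: list[str]
    class_order: tuple[str, str]
    priors: np.ndarray
    use_kernel: bool
    laplace_fl: float
    bandwidth_adjust: float
    points: Optional[dict] = None  # class -> feature -> training values
    bandwidths: Optional[dict] = None  # class -> feature -> float
    gaussians: Optional[dict] = None  # class -> feature -> (mean, sd)

    def _log_density(self, cls: str, X: pd.DataFrame) -> np.ndarray:
        total = np.zeros(len(X))
        for f in self.feature_names:
            x = X[f].to_numpy(dtype=float)
            if self.use_kernel:
                pts = np.asarray(self.points[cls][f])
                h = self.bandwidths[cls][f]
                dens = stats.norm.pdf((x[:, None] - pts[None, :]) / h).mean(axis=1) / h
            else:
                m, s = self.gaussians[cls][f]
                dens = stats.norm.pdf(x, loc=m, scale=s)
            total += np.log(np.maximum(dens, _DENSITY_FLOOR))
        return total

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior P(responder) per sample (row of X)."""
        X = X[self.feature_names] if self.feature_names else X
        log_post = np.stack(
            [np.log(self.priors[k]) + self._log_density(c, X) for k, c in enumerate(self.class_order)],
            axis=1,
        )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Hard responder call at 0.5; a tie at exactly 0.5 is called
        non-responder (conservative)."""
        return self.predict_proba(X) > 0.5

    def summary(self) -> str:
        lines = [
            "Kernel naive Bayes response classifier",
            "=" * 46,
            f"classes:            {self.class_order[0]} / {self.class_order[1]}",
            f"priors:             {self.priors[0]:.4f} / {self.priors[1]:.4f}",
            f"n features:         {len(self.feature_names)}",
            f"use_kernel:         {self.use_kernel}",
            f"laplace_fl:         {self.laplace_fl}",
            f"bandwidth_adjust:   {self.bandwidth_adjust}",
        ]
        if self.use_kernel:
            hs = [self.bandwidths[c][f] for c in self.class_order for f in self.feature_names]
            lines.append(f"median bandwidth:   {np.median(hs):.4g}")
        return "\n".join(lines)

    # -- JSON round-trip -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "class_order": list(self.class_order),
            "priors": self.priors.tolist(),
            "use_kernel": self.use_kernel,
            "laplace_fl": self.laplace_fl,
            "bandwidth_adjust": self.bandwidth_adjust,
            "points": {c: {f: np.asarray(v).tolist() for f, v in d.items()} for c, d in (self.points or {}).items()},
            "bandwidths": self.bandwidths,
            "gaussians": {c: {f: list(v) for f, v in d.items()} for c, d in (self.gaussians or {}).items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "KernelNBResults":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            feature_names=p["feature_names"],
            class_order=tuple(p["class_order"]),
            priors=np.asarray(p["priors"]),
            use_kernel=p["use_kernel"],
            laplace_fl=p["laplace_fl"],
            bandwidth_adjust=p["bandwidth_adjust"],
            points={c: {f: np.asarray(v) for f, v in d.items()} for c, d in p["points"].items()} or None,
            bandwidths=p["bandwidths"] or None,
            gaussians={c: {f: tuple(v) for f, v in d.items()} for c, d in p["gaussians"].items()} or None,
        )


class KernelNaiveBayes:
    """Model object: signature-restricted expression against responder labels.

    Parameters
    ----------
    X
        samples x features DataFrame (typically batch-corrected bulk
        expression restricted to the signature genes).
    y
        boolean responder labels aligned to X's rows.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[bool],
        use_kernel: bool = True,
        laplace_fl: float = 0.0,
        bandwidth_adjust: float = 0.75,
    ) -> None:
        self.X = pd.DataFrame(X)
        self.y = np.asarray(y, dtype=bool)
        if self.X.isna().to_numpy().any():
            raise ValueError("X contains NA features")
        if len(self.X) != len(self.y):
            raise ValueError("X and y must align")
        if self.y.all() or (~self.y).all():
            raise ValueError("both classes must be present in y")
        self.use_kernel = use_kernel
        self.laplace_fl = laplace_fl
        self.bandwidth_adjust = bandwidth_adjust

    def fit(self) -> KernelNBResults:
        y = self.y
        n = len(y)
        n_r, n_nr = int(y.sum()), int((~y).sum())
        fl = self.laplace_fl
        priors = np.array([(n_nr + fl) / (n + 2 * fl), (n_r + fl) / (n + 2 * fl)])
        classes = {"NR": ~y, "R": y}
        vals = self.X.to_numpy(dtype=float)
        global_sd = float(vals.std()) if vals.size else 0.0

        points: dict = {"NR": {}, "R": {}}
        bandwidths: dict = {"NR": {}, "R": {}}
        gaussians: dict = {"NR": {}, "R": {}}
        for cls, maskc in classes.items():
            for f in self.X.columns:
                v = self.X.loc[maskc, f].to_numpy(dtype=float)
                if self.use_kernel:
                    h = _silverman(v) * self.bandwidth_adjust
                    if not h > 0:
                        h = 1e-6 * (global_sd + 1e-12)
                    points[cls][f] = v
                    bandwidths[cls][f] = float(h)
                else:
                    sd = v.std(ddof=1) if len(v) > 1 else 0.0
                    if sd <= 0:
                        sd = 1e-6 * (global_sd + 1e-12)
                    gaussians[cls][f] = (float(v.mean()), float(sd))
        return KernelNBResults(
            feature_names=[str(c) for c in self.X.columns],
            class_order=("NR", "R"),
            priors=priors,
            use_kernel=self.use_kernel,
            laplace_fl=fl,
            bandwidth_adjust=self.bandwidth_adjust,
            points=points if self.use_kernel else None,
            bandwidths=bandwidths if self.use_kernel else None,
            gaussians=gaussians if not self.use_kernel else None,
        )


def train_nb(
    X: pd.DataFrame,
    y: Sequence[bool],
    use_kernel: bool = True,
    laplace_fl: float = 0.0,
    bandwidth_adjust: float = 0.75,
) -> KernelNBResults:
    """Functional wrapper around ``KernelNaiveBayes(...).fit()``."""
    return KernelNaiveBayes(X, y, use_kernel, laplace_fl, bandwidth_adjust).fit()


def predict_response(model: KernelNBResults, X: pd.DataFrame) -> pd.DataFrame:
    """Posterior P(responder) and hard label per sample."""
    post = model.predict_proba(X)
    return pd.DataFrame(
        {"p_responder": post, "label": np.where(post > 0.5, "R", "NR")}, index=X.index
    )


def tune_bandwidth(
    X: pd.DataFrame,
    y: Sequence[bool],
    grid: Sequence[float] = (0.5, 0.75, 1.0, 1.5),
    k: int = 5,
    seed: int = 0,
) -> float:
    """Pick bandwidth_adjust by k-fold cross-validated AUC."""
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, k)
    best, best_auc = grid[0], -np.inf
    for adj in grid:
        aucs = []
        for f in folds:
            test = np.zeros(len(y), dtype=bool)
            test[f] = True
            if y[~test].all() or (~y[~test]).all() or len(set(y[test])) < 2:
                continue
            m = train_nb(X.iloc[~test], y[~test], bandwidth_adjust=adj)
            aucs.append(roc_auc(m.predict_proba(X.iloc[test]), y[test]).auc)
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best, best_auc = adj, mean_auc
    return best


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float]


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 200,
    seed: int = 0,
) -> RocResult:
    """ROC curve and AUC (Mann-Whitney identity, ties counted 1/2) with a
    bootstrap confidence interval."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(set(y)) < 2:
        raise ValueError("labels must contain both classes")

    def _auc(sv: np.ndarray, yv: np.ndarray) -> float:
        r = stats.rankdata(sv)
        n1 = yv.sum()
        n0 = len(yv) - n1
        u = r[yv].sum() - n1 * (n1 + 1) / 2.0
        return float(u / (n1 * n0))

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, s)
    auc = _auc(s, y)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    for _ in range(n_boot):
        i = rng.integers(0, n, size=n)
        if len(set(y[i])) < 2:
            continue
        boots.append(_auc(s[i], y[i]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    return RocResult(thr, fpr, tpr, auc, ci)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _cox_two_group_breslow(
    times: np.ndarray, events: np.ndarray, group: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[float, float]:
    """Univariate proportional-hazards fit for a binary covariate.

    Newton-Raphson on the Breslow partial likelihood; returns (log HR,
    its standard error).
    """
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order].astype(bool), group[order].astype(float)
    beta = 0.0
    for _ in range(max_iter):
        theta = np.exp(beta * g)
        # risk set at each event time: all with time >= t_i
        score_num = 0.0
        info = 0.0
        # iterate over distinct event times (Breslow: tied events share one risk set)
        for ti in np.unique(t[e]):
            at_risk = t >= ti
            d = e & (t == ti)
            s0 = theta[at_risk].sum()
            s1 = (theta * g)[at_risk].sum()
            m = d.sum()
            score_num += (g[d].sum() - m * s1 / s0)
            info += m * (s1 / s0) * (1.0 - s1 / s0)
        if info <= 0:
            break
        step = score_num / info
        beta += step
        if abs(step) < tol:
            break
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    return float(beta), float(se)


@dataclass
class KmResult:
    """Two-group survival comparison: KM curves, log-rank test, hazard ratio."""

    curves: dict  # group -> DataFrame(time, survival)
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    medians: dict

    def summary(self) -> str:
        lines = ["Kaplan-Meier / log-rank / proportional hazards", "=" * 48]
        for grp, med in self.medians.items():
            med_txt = f"{med:.2f}" if np.isfinite(med) else "not reached"
            lines.append(f"median OS [{grp}]: {med_txt} months")
        lines.append(f"log-rank chi2 = {self.logrank_chi2:.3f}, p = {self.logrank_p:.3g}")
        lines.append(f"HR = {self.hr:.3f} (95% CI {self.hr_ci[0]:.3f}-{self.hr_ci[1]:.3f})")
        return "\n".join(lines)


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    reference: Optional[str] = None,
) -> KmResult:
    """Compare survival between two groups.

    Product-limit curves and the two-group log-rank test come from
    lifelines; the hazard ratio (non-reference group vs ``reference``,
    which defaults to the first level in sorted order) is a univariate
    proportional-hazards fit with Breslow tie handling.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = pd.Series(list(groups)).astype(str)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not among groups {levels}")
        levels = [reference, *[l for l in levels if l != reference]]
    if e.sum() == 0:
        raise ValueError("no events observed")
    for lev in levels:
        if e[(g == lev).to_numpy()].sum() == 0:
            raise ValueError(f"group {lev!r} has no events")

    curves, medians = {}, {}
    for lev in levels:
        m = (g == lev).to_numpy()
        kmf = KaplanMeierFitter().fit(t[m], e[m], label=lev)
        sf = kmf.survival_function_
        curves[lev] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf[lev].to_numpy()})
        medians[lev] = float(kmf.median_survival_time_)

    m0 = (g == levels[0]).to_numpy()
    lr = logrank_test(t[m0], t[~m0], e[m0], e[~m0])
    beta, se = _cox_two_group_breslow(t, e, (g == levels[1]).to_numpy())
    hr = float(np.exp(beta))
    with np.errstate(over="ignore"):  # separated groups give an unbounded CI
        ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
    return KmResult(curves, float(lr.test_statistic), float(lr.p_value), hr, ci, medians)
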