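"""Independent brute-force oracles used across the test suite.

Each function recomputes a quantity by the most literal route available
(enumeration, pairwise comparison, naive loops, or an unrelated library
code path) so the implementation under test is checked against an
independent definition, not against itself.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman R and t-approximation p via scipy's own implementation."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group labellings."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def geometric_mean_oracle(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def gsva_walk_oracle(
    x: np.ndarray,
    member_rows: list[int],
    tau: float = 1.0,
    mode: str = "max_dev",
) -> np.ndarray:
    """Naive loop re-derivation of the kernel-CDF + KS-walk score for
    every sample (column) of a small genes x samples matrix."""
    g, s = x.shape
    cdf = np.zeros_like(x, dtype=float)
    for i in range(g):
        sd = np.std(x[i], ddof=1)
        if sd <= 0:
            cdf[i] = 0.5
            continue
        h = sd / 4.0
        for j in range(s):
            cdf[i, j] = np.mean([stats.norm.cdf((x[i, j] - x[i, k]) / h) for k in range(s)])
    member = np.zeros(g, dtype=bool)
    member[member_rows] = True
    scores = np.zeros(s)
    for j in range(s):
        ranks = stats.rankdata(cdf[:, j])
        rstat = ranks - (g + 1) / 2.0
        order = sorted(range(g), key=lambda i: (-rstat[i], i))
        w_in = sum(abs(rstat[i]) ** tau for i in order if member[i])
        n_out = g - member.sum()
        v, run = [], 0.0
        for i in order:
            if member[i]:
                run += abs(rstat[i]) ** tau / w_in
            else:
                run -= 1.0 / n_out
            v.append(run)
        v = np.array(v)
        if mode == "max_dev":
            scores[j] = v[np.argmax(np.abs(v))]
        else:
            scores[j] = max(v.max(), 0.0) + min(v.min(), 0.0)
    return scores


def auc_pairwise_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by O(n^2) comparison of every positive/negative pair."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def fisher_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided over-representation p by direct hypergeometric tail sum.

    Table: a = in-both, b = sig only, c = top only, d = neither.
    """
    n = a + b + c + d
    k_sig = a + b
    k_top = a + c
    p = 0.0
    for x in range(a, min(k_sig, k_top) + 1):
        p += stats.hypergeom.pmf(x, n, k_sig, k_top)
    return p
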