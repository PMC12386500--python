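"""Nonparametric group comparisons across DIV.

Kruskal-Wallis omnibus test with mid-rank tie correction, followed by
Dunn's pairwise z-tests with multiplicity adjustment (Bonferroni over all
k(k-1)/2 pairs by default, matching the "multiplicity adjusted" behaviour
of common statistics software; Holm available).  Summaries are mean +- SD
per group with the usual significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWResult",
    "PairwiseComparison",
    "GroupTestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_metrics",
    "stars",
]


def stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float


def _check_groups(groups) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least 1 value")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 values in total")
    if any(not np.all(np.isfinite(g)) for g in groups):
        raise ValueError("non-finite values")
    return groups


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(
    groups,
    method: str = "chi2",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    H = [12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N)),
    with mid-ranks for ties.  ``method='chi2'`` uses the chi-square
    approximation with k-1 df; ``method='permutation'`` a seeded Monte-Carlo
    permutation null.  All values identical
    across all groups gives H = 0, p = 1 (not an error).
    """
    groups = _check_groups(groups)
    k = len(groups)
    df = k - 1

    def h_stat(gs) -> float:
        pooled = np.concatenate(gs)
        N = len(pooled)
        ranks = sps.rankdata(pooled)
        idx = 0
        rank_sums = []
        for g in gs:
            rank_sums.append(ranks[idx : idx + len(g)].sum())
            idx += len(g)
        h = 12.0 / (N * (N + 1)) * sum(
            rs**2 / len(g) for rs, g in zip(rank_sums, gs)
        ) - 3.0 * (N + 1)
        correction = 1.0 - _tie_term(pooled) / (N**3 - N)
        if correction <= 0:
            return 0.0  # all values tied everywhere
        return h / correction

    H = h_stat(groups)
    if H <= 0:
        H = max(H, 0.0)
    if method == "chi2":
        p = 1.0 if H == 0 else float(sps.chi2.sf(H, df))
    elif method == "permutation":
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            split = np.split(perm, np.cumsum(sizes)[:-1])
            if h_stat(split) >= H - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KWResult(float(H), df, min(1.0, p))


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: object
    group_j: object
    z: float
    p: float
    p_adjusted: float
    stars: str


def _adjust(pvals: np.ndarray, adjustment: str) -> np.ndarray:
    m = len(pvals)
    if adjustment == "none":
        return pvals.copy()
    if adjustment == "bonferroni":
        return np.minimum(1.0, pvals * m)
    if adjustment == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {adjustment!r}")


def dunn_posthoc(groups, adjustment: str = "bonferroni", labels=None) -> list[PairwiseComparison]:
    """Dunn's pairwise z-tests on pooled mid-ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
                                    * (1/n_i + 1/n_j))
    Two-sided normal p-values, adjusted over all pairs.
    """
    groups = _check_groups(groups)
    k = len(groups)
    labels = list(range(k)) if labels is None else list(labels)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    idx = 0
    mean_ranks = []
    for g in groups:
        mean_ranks.append(ranks[idx : idx + len(g)].mean())
        idx += len(g)
    var_term = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))

    pairs = list(combinations(range(k), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var_term * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(1.0 if se == 0 else float(2.0 * sps.norm.sf(abs(z))))
    adj = _adjust(np.asarray(ps), adjustment)
    return [
        PairwiseComparison(labels[i], labels[j], float(z), float(p), float(pa), stars(pa))
        for (i, j), z, p, pa in zip(pairs, zs, ps, adj)
    ]


@dataclass
class GroupTestResult:
    metric: str
    H: float
    df: int
    p_omnibus: float
    pairwise: list[PairwiseComparison]
    group_summaries: pd.DataFrame  # index: group label; columns: mean, sd, n
    n_invalid: int = 0

    def pair(self, a, b) -> PairwiseComparison:
        for c in self.pairwise:
            if {c.group_i, c.group_j} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a} and {b}")


def compare_metrics(
    table: pd.DataFrame,
    adjustment: str = "bonferroni",
    group_col: str = "div",
    metric_cols: list[str] | None = None,
) -> list[GroupTestResult]:
    """Kruskal-Wallis + Dunn for every metric column, grouped by DIV.

    Invalid (NaN) cells are excluded per metric with their counts recorded.
    A metric with fewer than 2 valid groups of n >= 2 raises.
    """
    if metric_cols is None:
        metric_cols = [
            c
            for c in table.columns
            if c not in (group_col, "sample_id", "bio_rep", "tech_rep")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    results = []
    for metric in metric_cols:
        sub = table[[group_col, metric]].dropna()
        n_invalid = len(table) - len(sub)
        labels = sorted(sub[group_col].unique())
        groups = [sub.loc[sub[group_col] == g, metric].to_numpy() for g in labels]
        if sum(len(g) >= 2 for g in groups) < 2:
            raise ValueError(f"metric {metric}: fewer than 2 groups with n >= 2")
        kw = kruskal_wallis(groups)
        pairwise = dunn_posthoc(groups, adjustment=adjustment, labels=labels)
        summaries = pd.DataFrame(
            {
                "mean": [g.mean() for g in groups],
                "sd": [g.std(ddof=1) if len(g) > 1 else np.nan for g in groups],
                "n": [len(g) for g in groups],
            },
            index=pd.Index(labels, name=group_col),
        )
        results.append(
            GroupTestResult(metric, kw.H, kw.df, kw.p, pairwise, summaries, n_invalid)
        )
    return results
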