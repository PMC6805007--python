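"""Tie-corrected rank statistics: Kruskal-Wallis, Dunn post hoc pairwise
tests, and the Mann-Whitney U test.

All three use mid-ranks for ties and the standard tie-correction terms.
Only these three tests are provided; they are the ones the surrounding
analyses need.  The Kruskal-Wallis p-value uses the chi-square approximation
with k-1 degrees of freedom (adequate at the group sizes encountered here,
and the convention the surrounding analyses assume); the Mann-Whitney p is
exact by enumeration for small samples without prohibitive cost, otherwise a
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = ["RankTestResult", "kruskal_wallis", "dunn_posthoc", "mann_whitney_u"]


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_two_sided: float
    group_sizes: tuple[int, ...]
    tie_correction: float
    df: int | None = None
    u1: float | None = None
    u2: float | None = None
    u_min: float | None = None
    method: str = ""


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(arrs)}")
    for i, a in enumerate(arrs):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    return arrs


def _tie_term(values: np.ndarray) -> float:
    """Sum over tied groups of t^3 - t."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H with tie correction.

    H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)]
    with mid-ranks for ties; p from chi-square with k-1 df.
    """
    arrs = _check_groups(groups, 2)
    all_values = np.concatenate(arrs)
    n = np.array([a.size for a in arrs])
    big_n = all_values.size
    if big_n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(all_values)
    h = 0.0
    start = 0
    for nk in n:
        h += ranks[start : start + nk].sum() ** 2 / nk
        start += nk
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(all_values) / (big_n**3 - big_n)
    if correction <= 0:  # all observations identical
        return RankTestResult(0.0, 1.0, tuple(n), 0.0 if correction <= 0 else correction,
                              df=len(arrs) - 1, method="kruskal-wallis")
    h /= correction
    h = max(h, 0.0)
    df = len(arrs) - 1
    p = float(chi2.sf(h, df))
    return RankTestResult(h, p, tuple(int(x) for x in n), correction, df=df,
                          method="kruskal-wallis")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    bonferroni: bool = False,
) -> list[dict]:
    """Dunn's pairwise z-tests on the joint mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]
    with tie term T = sum(t^3 - t) / (12(N-1)).  Two-sided p per pair,
    unadjusted by default (Bonferroni optional).
    """
    arrs = _check_groups(groups, 2)
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels length must match number of groups")
    all_values = np.concatenate(arrs)
    big_n = all_values.size
    ranks = rankdata(all_values)
    means = []
    start = 0
    for a in arrs:
        means.append(ranks[start : start + a.size].mean())
        start += a.size
    tie_t = _tie_term(all_values) / (12.0 * (big_n - 1))
    var_term = big_n * (big_n + 1) / 12.0 - tie_t
    n_pairs = len(arrs) * (len(arrs) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        se = np.sqrt(var_term * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        z = (means[i] - means[j]) / se if se > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z)))
        if bonferroni:
            p = min(1.0, p * n_pairs)
        out.append(
            dict(group_i=labels[i], group_j=labels[j], z=float(z), p_two_sided=p,
                 mean_rank_i=float(means[i]), mean_rank_j=float(means[j]))
        )
    return out


def _mwu_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled values
    into the two groups; correct under ties because the pooled multiset is
    fixed."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    big_n = pooled.size
    ranks = rankdata(pooled)
    u_null = []
    for idx in combinations(range(big_n), n1):
        r1 = ranks[list(idx)].sum()
        u_null.append(r1 - n1 * (n1 + 1) / 2.0)
    u_null = np.asarray(u_null)
    mean_u = n1 * (y.size) / 2.0
    # two-sided: as or more extreme in distance from the null mean
    dist = np.abs(u_null - mean_u)
    return float(np.mean(dist >= abs(u_obs - mean_u) - 1e-12))


def mann_whitney_u(
    group1: Sequence[float], group2: Sequence[float], exact_limit: int = 200
) -> RankTestResult:
    """Mann-Whitney U with both orientations.

    U1 counts pairwise wins of group1 plus half-ties (computed through the
    rank-sum identity).  p is exact by enumeration when n1*n2 <= exact_limit,
    else a tie-corrected normal approximation with continuity correction.
    """
    x, y = _check_groups([group1, group2], 2)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    tie = _tie_term(pooled)
    big_n = n1 + n2
    correction = 1.0 - tie / (big_n**3 - big_n) if big_n > 1 else 1.0
    from math import comb

    if n1 * n2 <= exact_limit and comb(big_n, n1) <= 20_000:
        p = _mwu_exact_p(x, y, u1)
        method = "exact"
    else:
        mean_u = n1 * n2 / 2.0
        var_u = n1 * n2 / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
        if var_u <= 0:
            p, method = 1.0, "normal"
        else:
            z = (abs(u1 - mean_u) - 0.5) / np.sqrt(var_u)
            p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
            method = "normal"
    return RankTestResult(
        statistic=u1,
        p_two_sided=p,
        group_sizes=(n1, n2),
        tie_correction=correction,
        u1=u1,
        u2=u2,
        u_min=min(u1, u2),
        method=f"mann-whitney-{method}",
    )
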