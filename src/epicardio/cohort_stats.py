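"""Group-comparison statistics: rank tests, effect sizes, correlations.

Conventions of the study's analysis plan: two-group comparisons by the
Wilcoxon rank-sum (Mann-Whitney) test, multi-group comparisons by
Kruskal-Wallis, proportions by a two-proportion test with Cohen's h as the
effect size, significance at p < 0.05, and no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import asin, sqrt

import numpy as np
from scipy import stats


class SampleError(ValueError):
    pass


class ConstantInputError(ValueError):
    pass


class UseRankSumInstead(ValueError):
    """Raised when Kruskal-Wallis is requested for fewer than 3 groups."""


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    effect_size: float = None
    n_per_group: tuple = None
    method: str = ""


def wilcoxon_rank_sum(a, b) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration over rank assignments (tie-aware) when both groups
    have n <= 8; otherwise the tie-corrected normal approximation with
    continuity correction.  The statistic reported is the Mann-Whitney U of
    the first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise SampleError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    if n1 <= 8 and n2 <= 8:
        # exact: enumerate all assignments of the pooled (tied) ranks
        us = np.array([sum(ranks[list(c)]) for c in combinations(range(n1 + n2), n1)])
        us -= n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        return ComparisonResult(float(u_obs), float(min(p, 1.0)),
                                n_per_group=(n1, n2), method="exact")
    if np.ptp(pooled) == 0:
        return ComparisonResult(float(u_obs), 1.0, n_per_group=(n1, n2),
                                method="asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            n_per_group=(n1, n2), method="asymptotic")


def kruskal_wallis(groups) -> ComparisonResult:
    """Kruskal-Wallis H test with tie correction; chi-square p, k−1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise UseRankSumInstead(
            "fewer than 3 groups: use wilcoxon_rank_sum instead")
    if any(len(g) < 2 for g in groups):
        raise SampleError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return ComparisonResult(0.0, 1.0, n_per_group=tuple(map(len, groups)),
                                method="kruskal")
    h, p = stats.kruskal(*groups)
    return ComparisonResult(float(h), float(p),
                            n_per_group=tuple(map(len, groups)), method="kruskal")


def cohens_h(p1: float, p2: float) -> float:
    """Effect size for two proportions: |2·asin(sqrt(p1)) − 2·asin(sqrt(p2))|."""
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return abs(2 * asin(sqrt(p1)) - 2 * asin(sqrt(p2)))


def proportion_test(k1, n1, k2, n2) -> ComparisonResult:
    """Two-proportion comparison on arcsine-transformed proportions.

    The study's phrasing ("proportions were tested by the T test") is
    unusual; this implements a z test on the variance-stabilizing arcsine
    scale and reports Cohen's h alongside, as documented in the methods
    note.
    """
    if min(n1, n2) < 1 or not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise SampleError("invalid counts")
    p1, p2 = k1 / n1, k2 / n2
    h = 2 * asin(sqrt(p1)) - 2 * asin(sqrt(p2))
    se = sqrt(1 / n1 + 1 / n2)
    z = h / se
    p = 2 * stats.norm.sf(abs(z))
    return ComparisonResult(float(z), float(p), effect_size=abs(h),
                            n_per_group=(n1, n2), method="arcsine-z")


def correlations(x, y, method="pearson"):
    """Pearson or Spearman correlation with its p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise SampleError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def compare_groups(table, measures, group_col="group", groups=None):
    """Pairwise rank-sum comparison report across measures.

    Returns a DataFrame with one row per measure: statistic, p-value and
    group ns, for the two groups given (default: the two labels present).
    """
    import pandas as pd

    if groups is None:
        groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise SampleError("compare_groups expects exactly two groups")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []
    for m in measures:
        res = wilcoxon_rank_sum(ga[m].to_numpy(), gb[m].to_numpy())
        rows.append({"measure": m, "group_a": groups[0], "group_b": groups[1],
                     "mean_a": ga[m].mean(), "mean_b": gb[m].mean(),
                     "statistic": res.statistic, "p": res.p_value,
                     "n_a": len(ga), "n_b": len(gb)})
    return pd.DataFrame(rows)
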