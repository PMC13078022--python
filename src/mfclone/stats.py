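"""Elementary two-sided group-comparison statistics.

Numeric features are compared by Mann-Whitney U (two groups; exact
enumeration when the pooled sample size is <= 10, tie-corrected normal
approximation otherwise) or Kruskal-Wallis (three or more groups).
Categorical features use Fisher's exact test (2x2, two-sided by the
probability-mass rule) or the chi-squared test without continuity
correction for larger tables.  No multiple-testing correction is applied
by default; a Benjamini-Hochberg helper is provided for exploratory
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_MW_MAX_N = 10


@dataclass
class GroupComparison:
    feature: str
    test: str  # mann_whitney | kruskal_wallis | fisher | chi_squared
    statistic: float
    p_value: float
    group_summaries: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x vs y with half-credit for ties."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Handles ties naturally (permutation of the observed pooled values).
    The null U distribution is symmetric about n1*n2/2, so the two-sided p
    sums both tails at the observed deviation from the center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    u_obs = _mann_whitney_u(x, y)
    center = len(x) * len(y) / 2.0
    dev = abs(u_obs - center)
    total = comb(n, n1)
    hits = 0
    idx = np.arange(n)
    for group1 in combinations(idx, n1):
        g1 = pooled[list(group1)]
        g2 = np.delete(pooled, list(group1))
        u = _mann_whitney_u(g1, g2)
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def compare_numeric_groups(
    groups: Mapping[str, Sequence[float]],
    feature: str = "",
    test: Optional[str] = None,
) -> GroupComparison:
    """Two-sided comparison of a numeric feature across labeled groups.

    Two groups route to Mann-Whitney U (exact when pooled n <= 10), three
    or more to Kruskal-Wallis.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(list(groups[g]), dtype=float) for g in names}
    for g, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
    summaries = {
        g: {"n": int(arr.size), "median": float(np.median(arr))}
        for g, arr in arrays.items()
    }
    if test is None:
        test = "mann_whitney" if len(names) == 2 else "kruskal_wallis"
    if test == "mann_whitney":
        if len(names) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        x, y = arrays[names[0]], arrays[names[1]]
        if len(x) + len(y) <= EXACT_MW_MAX_N:
            stat, p = mann_whitney_exact(x, y)
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        res = sps.kruskal(*[arrays[g] for g in names])
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown numeric test {test!r}")
    return GroupComparison(
        feature=feature, test=test, statistic=stat, p_value=min(p, 1.0),
        group_summaries=summaries,
    )


def compare_categorical_groups(
    table: Sequence[Sequence[int]],
    feature: str = "",
    test: Optional[str] = None,
) -> GroupComparison:
    """Two-sided test on a contingency table of non-negative counts.

    2x2 tables route to Fisher's exact test (probability-mass rule);
    larger tables to chi-squared without continuity correction.
    """
    arr = np.asarray(table, dtype=int)
    if (arr < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if test is None:
        test = "fisher" if arr.shape == (2, 2) else "chi_squared"
    if test == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 table")
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
        stat = float(odds) if np.isfinite(odds) else float("inf")
    elif test == "chi_squared":
        res = sps.chi2_contingency(arr, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown categorical test {test!r}")
    summaries = {
        f"row{i}": {"counts": arr[i].tolist(), "n": int(arr[i].sum())}
        for i in range(arr.shape[0])
    }
    return GroupComparison(
        feature=feature, test=test, statistic=stat, p_value=float(min(p, 1.0)),
        group_summaries=summaries,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted q-values (optional, for exploratory tables)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out.tolist()
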