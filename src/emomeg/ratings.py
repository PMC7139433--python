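"""Group comparison of per-picture median emotion ratings.

For each stimulus category and rating dimension (valence, arousal on the
7-point SAM scale, valence 1 = most pleasant), the median rating of each
picture is computed within each group over the complete raters only, and the
two per-picture median vectors are compared with the two-sided Wilcoxon
rank-sum test.  Even-cardinality medians use the mean-of-middle-two
convention, so half-integer medians occur and are handled by the rank test.
No multiplicity correction is applied across the six comparisons; the
report flags the p-values as raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIMENSIONS = ("valence", "arousal")
EXACT_MAX_N = 12


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum outcome for one category x dimension."""

    statistic: float  # rank sum of the first sample
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    method: str  # "exact" or "asymptotic"


def complete_subjects(table: pd.DataFrame) -> list[str]:
    """Subjects who rated every picture (full participation)."""
    n_pictures = table["picture_id"].nunique()
    counts = table.groupby("subject_id")["picture_id"].nunique()
    return sorted(counts.index[counts == n_pictures])


def per_picture_medians(
    table: pd.DataFrame, group: int, category: str, dimension: str
) -> pd.Series:
    """Median rating per picture across one group's complete subjects."""
    if dimension not in DIMENSIONS:
        raise ValueError(f"dimension must be one of {DIMENSIONS}")
    keep = table[table["subject_id"].isin(complete_subjects(table))]
    sub = keep[(keep["group"] == group) & (keep["category"] == category)]
    if sub.empty:
        raise ValueError(f"no complete raters for group {group}, category {category!r}")
    medians = sub.groupby("picture_id")[dimension].median()
    n_pictures = keep.loc[keep["category"] == category, "picture_id"].nunique()
    if len(medians) != n_pictures:
        raise ValueError(
            f"some pictures of category {category!r} have zero raters in group {group}"
        )
    return medians.sort_index()


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution when the pooled sample is small
    (``n1 + n2 <= 12``) and tie-free, otherwise the normal approximation
    with tie and continuity corrections.  Identical constant samples give
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = stats.rankdata(pooled)
    statistic = float(np.sum(ranks[:n1]))

    if np.all(pooled == pooled[0]):
        p = 1.0
        method = "degenerate"
    elif n1 + n2 <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(res.pvalue, 1.0))
        method = "asymptotic"
    return RankSumResult(
        statistic=statistic,
        p_value=p,
        n1=n1,
        n2=n2,
        median1=float(np.median(a)),
        median2=float(np.median(b)),
        method=method,
    )


def compare_groups(
    table: pd.DataFrame, group_a: int = 1, group_b: int = 0
) -> pd.DataFrame:
    """All category x dimension rank-sum comparisons of per-picture medians.

    Returns a tidy frame (one row per test) with sample sizes, the rank-sum
    statistic of group ``group_a`` (controls by default), the raw two-sided
    p-value and each group's median of per-picture medians.
    """
    categories = list(dict.fromkeys(table["category"]))
    if not categories:
        raise ValueError("rating table is empty")
    rows = []
    for category in categories:
        for dimension in DIMENSIONS:
            a = per_picture_medians(table, group_a, category, dimension)
            b = per_picture_medians(table, group_b, category, dimension)
            res = rank_sum_test(a.to_numpy(), b.to_numpy())
            rows.append(
                {
                    "category": category,
                    "dimension": dimension,
                    "n1": res.n1,
                    "n2": res.n2,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "median_group1": res.median1,
                    "median_group0": res.median2,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
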