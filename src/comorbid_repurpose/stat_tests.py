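"""Shared exact/approximate test statistics.

Policy for the one-sided rank-sum comparison used throughout: the exact
null distribution when both groups are small (<= 12) and the pooled
sample is tie-free; direct enumeration of group assignments (mid-ranks)
when ties are present but the pooled sample is small enough to enumerate;
and the normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_greater", "hypergeom_overlap_p", "bh_adjust"]

EXACT_MAX = 12
ENUM_TOTAL_MAX = 12  # pooled-size cap for brute-force enumeration with ties


def _enumerate_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided p by enumerating all group assignments (mid-ranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    observed = ranks[: x.size].sum()
    total = 0
    hits = 0
    for idx in combinations(range(pooled.size), x.size):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


def rank_sum_greater(
    x: np.ndarray | list,
    y: np.ndarray | list,
    exact_max: int = EXACT_MAX,
) -> float:
    """One-sided (greater) Wilcoxon rank-sum p-value for x versus y.

    Exact when both samples have at most ``exact_max`` observations and
    the pooled sample is tie-free; exact by assignment enumeration when
    ties are present but the pooled sample has at most
    ``ENUM_TOTAL_MAX`` observations; otherwise the normal approximation
    with mid-ranks, tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_greater requires two non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= exact_max and y.size <= exact_max:
        method = "exact"
    elif has_ties and pooled.size <= ENUM_TOTAL_MAX:
        return _enumerate_rank_sum_p(x, y)
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def hypergeom_overlap_p(
    n_overlap: int, n_set_a: int, n_set_b: int, n_universe: int
) -> float:
    """One-sided enrichment p: P(X >= n_overlap) under the hypergeometric.

    Equivalent to the one-sided Fisher exact test of the 2x2 overlap
    table.  Symmetric in the two set sizes.
    """
    if n_overlap < 0 or n_set_a > n_universe or n_set_b > n_universe:
        raise ValueError("invalid overlap configuration")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))


def bh_adjust(pvalues: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
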