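"""Shared statistical helpers (rank-sum tests, 2x2 chi-squared, BH adjustment)."""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries are left NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def rank_sum_test(x, y, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for small tie-free samples (both n <= ``exact_max``),
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= exact_max and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def chi2_2x2(table) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared for a 2x2 table.

    Degenerate tables (a zero row or column margin) carry no information about
    association; they return (0.0, 1.0) instead of raising.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi2_2x2 expects a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def expected_counts_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        return np.zeros((2, 2))
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n
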