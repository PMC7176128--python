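"""Cohort-level statistics: paired Wilcoxon tests, BH-FDR, Spearman matrix.

The study's statistical layer: two-sided Wilcoxon signed-rank tests for
paired per-lesion readings (exact permutation null for small samples,
scipy's normal approximation with tie and continuity corrections beyond),
Benjamini–Hochberg step-up adjustment over an explicitly supplied family
of p-values, and a pairwise Spearman rank-correlation matrix across
imaging parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_BELOW_DEFAULT = 25


class DegenerateDataError(ValueError):
    """All paired differences are zero."""


@dataclass(frozen=True)
class StatTestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None


def _exact_signed_rank_p(diff: np.ndarray) -> float:
    """Exact two-sided p over the 2^n equiprobable sign assignments.

    Ranks of |d| use average ranks for ties; doubling them makes every rank
    an integer, so the null distribution of the (doubled) positive-rank sum
    W+ follows from a subset-sum count recursion — O(n·Σranks), exact for
    any n this test meets in practice.
    """
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(diff))).astype(int)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        counts[r:] += counts[:-r].copy() if r else counts.copy()
    n_assign = 2.0 ** diff.size
    w_plus = int(ranks2[diff > 0].sum())
    cdf = counts[: w_plus + 1].sum() / n_assign
    sf = counts[w_plus:].sum() / n_assign
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(paired_a, paired_b,
                         exact_below: int = EXACT_BELOW_DEFAULT,
                         name: str = "wilcoxon") -> StatTestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original convention). The
    exact permutation null is enumerated when at most ``exact_below`` pairs
    remain; beyond that the normal approximation with tie and continuity
    corrections is used. The reported statistic is W = min(W+, W−), the
    smaller of the signed-rank sums.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0.0]
    if diff.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if diff.size < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(diff))
    w = float(min(ranks[diff > 0].sum(), ranks[diff < 0].sum()))
    if diff.size <= exact_below:
        p = _exact_signed_rank_p(diff)
    else:
        p = float(stats.wilcoxon(diff, zero_method="wilcox", correction=True,
                                 alternative="two-sided", method="approx").pvalue)
    return StatTestResult(name=name, statistic=w, p_value=p,
                          n=int(diff.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(tests: list[StatTestResult]) -> list[StatTestResult]:
    """BH-adjust exactly the supplied family of tests (explicit scope)."""
    adj = bh_fdr([t.p_value for t in tests])
    return [StatTestResult(name=t.name, statistic=t.statistic,
                           p_value=t.p_value, n=t.n, p_adjusted=float(q))
            for t, q in zip(tests, adj)]


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations across the table's columns.

    Average ranks for ties, p-values from the t approximation. Returns
    (rho, p) DataFrames indexed by column name; a constant column yields
    NaN against every other column (undefined correlation), flagged rather
    than raised so one degenerate parameter does not sink the matrix.
    """
    if table.shape[0] < 5:
        raise ValueError("need at least 5 rows")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 parameters")
    if table.isna().any().any():
        raise ValueError("missing values not supported")
    cols = list(table.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = table[cols[i]].to_numpy()
            xj = table[cols[j]].to_numpy()
            if np.unique(xi).size == 1 or np.unique(xj).size == 1:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))
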