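"""Shared statistical primitives: rank-sum tests and FDR control.

The Wilcoxon rank-sum (Mann-Whitney U) test is the workhorse significance
test of the pipeline.  Policy:

* small untied groups  -> exact null distribution (scipy ``method="exact"``)
* small tied groups    -> exact p by enumeration of all group assignments
* otherwise            -> normal approximation with tie correction and
                          continuity correction

"Small" means both group sizes are at most ``EXACT_MAX`` (20).  Enumeration
is only attempted when the smaller group has at most ``ENUM_MAX`` (8)
observations, which keeps the combinatorial count manageable.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

EXACT_MAX = 20
ENUM_MAX = 8


def _rank_sum_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for the rank-sum statistic by full enumeration.

    Enumerates every assignment of the pooled observations into groups of
    the observed sizes and compares the rank sum of the smaller group.
    Handles ties through midranks.  Cost is C(n+m, min(n, m)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) > len(y):  # enumerate over the smaller group
        x, y = y, x
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, total = len(x), len(pooled)
    observed = ranks[:n].sum()
    mean = n * (total + 1) / 2.0
    dev = abs(observed - mean)
    hits = 0
    for idx in combinations(range(total), n):
        if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-9:
            hits += 1
    return hits / comb(total, n)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(statistic, p_value)`` where the statistic is the
    Mann-Whitney U of the first group.  Dispatches between exact and
    asymptotic computation as described in the module docstring.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return np.nan, 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0
    small = max(len(x), len(y)) <= EXACT_MAX
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and min(len(x), len(y)) <= ENUM_MAX:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), _rank_sum_enumeration_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def rank_sum_test_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for genes x cells blocks.

    ``x`` is (n_genes, n1), ``y`` is (n_genes, n2).  Uses the vectorised
    asymptotic test when both groups exceed ``EXACT_MAX`` cells, otherwise
    falls back to the per-row scalar policy.  Constant rows get p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    if min(n1, n2) == 0:
        return np.ones(x.shape[0])
    if max(n1, n2) > EXACT_MAX:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                x, y, axis=1, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
        p = np.asarray(res.pvalue, dtype=float)
        constant = np.ptp(np.concatenate([x, y], axis=1), axis=1) == 0
        p[constant] = 1.0
        p[~np.isfinite(p)] = 1.0
        return p
    return np.array([rank_sum_test(x[i], y[i])[1] for i in range(x.shape[0])])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def fisher_exact_with_log_odds(table) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test plus a log-odds ratio.

    Returns ``(log_odds, p_value, haldane_corrected)``.  When any cell is
    zero the log-odds uses the Haldane-Anscombe +0.5 correction (flagged);
    the exact p-value is computed on the uncorrected table.
    """
    t = np.asarray(table, dtype=float)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    log_odds = float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))
    return log_odds, float(p), corrected
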