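"""Small-sample nonparametric statistics.

Two-group comparisons use the two-tailed Mann-Whitney U test with the exact
null distribution obtained by enumeration (feasible and preferable for the
cohort sizes of interest, n1 + n2 <= 25). Three paired conditions are compared
with the Friedman rank test followed by Dunn's pairwise z-tests with Bonferroni
adjustment. Normality screening uses Shapiro-Wilk; summaries are reported as
median [IQR] or mean (s.d.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoSampleResult",
    "FriedmanDunnResult",
    "mann_whitney_exact",
    "exact_u_null_counts",
    "exact_p_two_sided",
    "friedman_dunn",
    "normality_check",
    "summarize",
]

#: exact enumeration is used up to this combined sample size (and no ties)
EXACT_LIMIT = 25


@dataclass
class TwoSampleResult:
    """Result of a two-tailed Mann-Whitney U comparison."""

    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal-approx"


@dataclass
class FriedmanDunnResult:
    """Friedman omnibus test plus Dunn's Bonferroni-adjusted post-hoc."""

    chi2: float
    df: int
    p_omnibus: float
    pairwise: pd.DataFrame  # columns: i, j, mean_rank_diff, z, p_adjusted


@lru_cache(maxsize=None)
def exact_u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of group labelings yielding each U value under the null.

    Returns a tuple ``c`` of length ``n1*n2 + 1`` where ``c[u]`` is the number
    of the C(n1+n2, n1) equally likely rank assignments with statistic U = u.
    ``c[u]`` equals the number of integer partitions of ``u`` into at most
    ``n1`` parts, each at most ``n2`` (the Gaussian-binomial coefficients),
    built by the standard two-way recurrence.
    """
    # f[m][n][u], computed iteratively over m with python ints (no overflow)
    prev = [[1] + [0] * (n1 * n2) for _ in range(n2 + 1)]  # m = 0
    for m in range(1, n1 + 1):
        cur = [[0] * (n1 * n2 + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1
        for n in range(1, n2 + 1):
            row = cur[n]
            rown1 = cur[n - 1]
            prow = prev[n]
            for u in range(m * n + 1):
                row[u] = prow[u] + (rown1[u - m] if u >= m else 0)
        prev = cur
    return tuple(prev[n2])


def exact_p_two_sided(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p-value: 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    counts = exact_u_null_counts(n1, n2)
    total = sum(counts)
    lo = math.floor(u)
    hi = math.ceil(u)
    p_le = sum(counts[: lo + 1]) / total
    p_ge = sum(counts[hi:]) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i < y_j} + 0.5 * #{(i,j): x_i == y_j}."""
    diff = y[None, :] - x[:, None]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_exact(x, y) -> TwoSampleResult:
    """Two-tailed Mann-Whitney U test for two independent samples.

    The exact null distribution (enumeration over all C(n1+n2, n1) labelings)
    is used when ``n1 + n2 <= 25`` and the pooled data contain no ties;
    otherwise the normal approximation with tie-corrected variance is used and
    flagged in ``method``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        p = exact_p_two_sided(u, n1, n2)
        return TwoSampleResult(U=u, n1=n1, n2=n2, p_two_sided=p, method="exact")
    # normal approximation with tie correction
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return TwoSampleResult(U=u, n1=n1, n2=n2, p_two_sided=1.0, method="normal-approx")
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TwoSampleResult(U=u, n1=n1, n2=n2, p_two_sided=float(p), method="normal-approx")


def friedman_dunn(data) -> FriedmanDunnResult:
    """Friedman rank test over an n x k matrix of paired measurements,
    followed by Dunn's pairwise z-tests with Bonferroni adjustment.

    Each row is one subject measured under all k conditions (mid-ranks on
    ties). The omnibus statistic is

        chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

    referred to chi-square with k-1 df. Dunn's z for conditions i, j is
    |Rbar_i - Rbar_j| / sqrt(k(k+1)/(6n)); two-sided p-values are multiplied
    by the number of pairs m = k(k-1)/2 and capped at 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported; rows must be complete")
    n, k = data.shape
    if k < 3:
        raise ValueError("need k >= 3 conditions")
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    df = k - 1
    p_omnibus = float(sps.chi2.sf(chi2, df))
    mean_ranks = col_sums / n
    m = k * (k - 1) // 2
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = abs(mean_ranks[i] - mean_ranks[j])
            z = d / se
            p_adj = min(1.0, m * 2.0 * float(sps.norm.sf(z)))
            rows.append({"i": i, "j": j, "mean_rank_diff": d, "z": z, "p_adjusted": p_adj})
    return FriedmanDunnResult(
        chi2=float(chi2), df=df, p_omnibus=p_omnibus, pairwise=pd.DataFrame(rows)
    )


def normality_check(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test. Returns (W, p).

    Requires 3 <= n <= 2000; a constant sample is degenerate (W undefined)
    and raises.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 3 <= len(x) <= 2000:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 2000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: W is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def summarize(x, mode: str = "median_iqr") -> dict:
    """Summary record: ``median_iqr`` -> median with 25th/75th percentiles
    (linear interpolation), ``mean_sd`` -> mean with sample s.d. (ddof=1)."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty sample")
    if mode == "median_iqr":
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        return {"mode": mode, "n": len(x), "median": float(med), "q25": float(q25), "q75": float(q75)}
    if mode == "mean_sd":
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return {"mode": mode, "n": len(x), "mean": float(np.mean(x)), "sd": sd}
    raise ValueError(f"unknown mode {mode!r}")
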