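"""Cohort-level statistics: rank tests, Pearson correlation, inter-reader ICC.

The rank tests mirror common commercial-software behaviour: the Mann-Whitney
U p-value is computed by exact enumeration for small samples (combined
n <= 20) and by the tie-corrected normal approximation with continuity
correction otherwise; Kruskal-Wallis is tie-corrected with a chi-square
reference.  Pearson correlations carry Fisher-z confidence intervals.  The
inter-reader ICC is the two-way random-effects, absolute-agreement,
single-measurement form (ICC(A,1) in the McGraw-Wong taxonomy) — the
standard choice for reliability of one continuous measurement per reader.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import scipy.stats as ss

__all__ = [
    "MannWhitneyResult",
    "CorrelationResult",
    "ICCResult",
    "mann_whitney",
    "kruskal_wallis",
    "pearson",
    "icc_inter_reader",
    "group_summary",
]

EXACT_MAX_N = 20  # combined-sample bound for exact enumeration


@dataclasses.dataclass(frozen=True)
class MannWhitneyResult:
    u: float           # U statistic of the first group
    p: float           # two-sided
    method: str        # "exact" or "normal"
    n1: int
    n2: int


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclasses.dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: #(a > b) pairs, ties counting 1/2."""
    ranks = ss.rankdata(np.concatenate([a, b]))
    n1 = a.size
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(
    a,
    b,
    use_continuity: bool = True,
    method: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method``: "exact" enumerates the permutation distribution of U over
    all assignments of the pooled values to groups (ties handled by
    midranks); "normal" is the tie-corrected Gaussian approximation, with
    continuity correction if ``use_continuity``; "auto" picks exact when the
    combined sample is at most 20 values.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if n1 + n2 <= EXACT_MAX_N else "normal"
    if method == "exact":
        p = _exact_mw_p(a, b, u)
    elif method == "normal":
        p = _normal_mw_p(a, b, u, use_continuity)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MannWhitneyResult(u=u, p=p, method=method, n1=n1, n2=n2)


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Works with ties: U is computed from midranks of the pooled sample, so
    the null distribution is the permutation distribution of the tie-aware
    statistic.  Two-sided p is the probability of a U at least as far from
    its null mean n1*n2/2 as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    n1, n = a.size, pooled.size
    offset = n1 * (n1 + 1) / 2.0
    center = a.size * b.size / 2.0
    d_obs = abs(u_obs - center) - 1e-12   # guard float fuzz at equality
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - center) >= d_obs:
            hits += 1
    return hits / total


def _normal_mw_p(a, b, u, use_continuity: bool) -> float:
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:          # all values identical
        return 1.0
    mean = n1 * n2 / 2.0
    d = abs(u - mean)
    if use_continuity:
        d = max(d - 0.5, 0.0)
    z = d / math.sqrt(var)
    return float(2.0 * ss.norm.sf(z))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    All-identical data across every group is not an error: H = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = ss.kruskal(*arrays)
    return float(h), float(p)


def pearson(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = ss.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zc = ss.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(r=float(r), ci_low=float(lo), ci_high=float(hi),
                             p=float(p), n=n)


def icc_inter_reader(reader1, reader2, level: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA decomposition over n subjects x 2
    readers; the confidence interval follows the F-based construction of
    McGraw & Wong with Satterthwaite degrees of freedom.
    """
    y1 = np.asarray(reader1, dtype=float).ravel()
    y2 = np.asarray(reader2, dtype=float).ravel()
    if y1.size != y2.size:
        raise ValueError("readers must have equal-length paired measurements")
    n = y1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    y = np.column_stack([y1, y2])
    k = 2
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    alpha = 1.0 - level
    if mse == 0 and msc == 0:      # perfect agreement
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, n=n)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    bb = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + bb * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1)))
        f_u = ss.f.ppf(1 - alpha / 2, v, n - 1)
        f_l = ss.f.ppf(1 - alpha / 2, n - 1, v)
        lo = (n * (msr - f_l * mse)
              / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_u * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    else:
        lo, hi = 1.0, 1.0
    return ICCResult(icc=float(icc), ci_low=float(min(lo, icc)),
                     ci_high=float(max(hi, icc)), n=n)


def group_summary(df: pd.DataFrame, value_col: str, group_col: str
                  ) -> pd.DataFrame:
    """Per-group mean, SD, median, IQR and n for one metric column."""
    rows = []
    for name, sub in df.groupby(group_col, sort=False):
        v = sub[value_col].dropna().to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75]) if v.size else (
            np.nan,) * 3
        rows.append({
            group_col: name,
            "n": v.size,
            "mean": v.mean() if v.size else np.nan,
            "sd": v.std(ddof=1) if v.size > 1 else np.nan,
            "median": med,
            "iqr_low": q1,
            "iqr_high": q3,
        })
    return pd.DataFrame(rows)
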