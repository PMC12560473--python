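"""Empirical ROC analysis, cutoff tables, Wilson intervals, likelihood ratios.

The cutoff table mirrors the diagnostic-test tables of commercial statistics
packages: one row per candidate threshold with the strict "> threshold"
rule, sensitivity and specificity as exact count fractions with 95%
confidence intervals, and the positive likelihood ratio
``LR+ = sens / (1 - spec)`` computed on the exact fractions before rounding.

Two interval flavours are provided.  ``wilson_ci`` is the plain Wilson score
interval.  ``wilson_brown_ci`` additionally applies the Brown-Cai-DasGupta
boundary modification — when the success or failure count is at most 2, the
near-boundary limit is replaced by the one-sided Poisson (chi-square) bound
``chi2(alpha; 2c) / (2n)`` — which is the hybrid used by widely-deployed
commercial software and differs from plain Wilson only in those extreme
rows.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "CutoffRow",
    "roc",
    "cutoff_table",
    "wilson_ci",
    "wilson_brown_ci",
    "likelihood_ratio",
    "auc_from_mann_whitney",
    "delong_auc_ci",
]


@dataclasses.dataclass
class ROCResult:
    """Empirical ROC curve and trapezoidal AUC.

    The curve runs from (0,0) to (1,1); AUC equals the Mann-Whitney
    probability that a random positive outscores a random negative (ties
    contribute 1/2).
    """

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    positive_direction: str    # "greater": higher values indicate positives


@dataclasses.dataclass(frozen=True)
class CutoffRow:
    """One "> threshold" row: point estimates in %, Wilson 95% CIs, LR+."""

    threshold: float
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    likelihood_ratio: float    # may be inf when specificity is 100%
    tp: int
    fn: int
    tn: int
    fp: int


def _validate_binary(values, labels):
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"need both classes 0 and 1; got labels {classes.tolist()}")
    return values, labels


def roc(values, labels, positive_direction: str = "greater") -> ROCResult:
    """Empirical ROC over all distinct thresholds, trapezoidal AUC.

    ``positive_direction="greater"`` means higher values indicate the
    positive class (label 1); "less" negates the scores.  The orientation is
    explicit and never auto-flipped: an AUC below 0.5 is reported as such.
    """
    values, labels = _validate_binary(values, labels)
    if positive_direction not in ("greater", "less"):
        raise ValueError("positive_direction must be 'greater' or 'less'")
    scores = values if positive_direction == "greater" else -values
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr,
                     positive_direction=positive_direction)


def auc_from_mann_whitney(values, labels) -> float:
    """AUC via the rank identity U/(n1*n2), ties contributing 1/2."""
    values, labels = _validate_binary(values, labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    ranks = ss.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct observed values."""
    v = np.unique(np.asarray(values, dtype=float).ravel())
    if v.size < 2:
        return np.array([])
    return (v[:-1] + v[1:]) / 2.0


def wilson_ci(successes: int, n: int, level: float = 0.95
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    z = ss.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half) * 100.0,
            min(1.0, center + half) * 100.0)


def wilson_brown_ci(successes: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Wilson interval with the Poisson boundary modification, in percent.

    For a boundary count ``c = successes`` (lower limit) or ``c = n -
    successes`` (upper limit) with ``1 <= c <= 2``, the corresponding Wilson
    limit is replaced by the one-sided chi-square/Poisson bound
    ``chi2.ppf(alpha, 2c) / (2n)`` (lower) or its mirror (upper), where
    ``alpha = 1 - level``.  Elsewhere the plain Wilson limits are kept.
    """
    lo, hi = wilson_ci(successes, n, level)
    alpha = 1.0 - level
    c_lo = successes
    c_hi = n - successes
    if 1 <= c_lo <= 2:
        lo = ss.chi2.ppf(alpha, 2 * c_lo) / (2.0 * n) * 100.0
    if 1 <= c_hi <= 2:
        hi = (1.0 - ss.chi2.ppf(alpha, 2 * c_hi) / (2.0 * n)) * 100.0
    return lo, hi


def likelihood_ratio(sens: Fraction | float, spec: Fraction | float) -> float:
    """Positive likelihood ratio ``sens / (1 - spec)`` on exact fractions.

    Pass count fractions (``Fraction(21, 30)``) to avoid rounding: the
    display-precision LR of a table row is then exactly reproducible.
    Specificity of 1 yields ``inf``.
    """
    sens_f = Fraction(sens) if not isinstance(sens, Fraction) else sens
    spec_f = Fraction(spec) if not isinstance(spec, Fraction) else spec
    if not (0 <= sens_f <= 1 and 0 <= spec_f <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if spec_f == 1:
        return math.inf
    return float(sens_f / (1 - spec_f))


def cutoff_table(
    values,
    labels,
    thresholds=None,
    positive_direction: str = "greater",
    level: float = 0.95,
    ci_method: str = "wilson",
) -> list[CutoffRow]:
    """Diagnostic cutoff table with the strict "> threshold" rule.

    ``thresholds=None`` uses all midpoints between consecutive distinct
    values (so any printed cutoff between two observations is representable).
    A threshold outside the data range still yields a row, with degenerate
    sensitivity or specificity.  ``ci_method`` is "wilson" or "wilson_brown".
    """
    values, labels = _validate_binary(values, labels)
    scores = values if positive_direction == "greater" else -values
    if thresholds is None:
        thr = candidate_thresholds(scores)
    else:
        thr = np.asarray(thresholds, dtype=float).ravel()
        if positive_direction == "less":
            thr = -thr
    ci = {"wilson": wilson_ci, "wilson_brown": wilson_brown_ci}[ci_method]
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rows = []
    for t in thr:
        tp = int(np.count_nonzero(pos > t))
        fn = pos.size - tp
        tn = int(np.count_nonzero(neg <= t))
        fp = neg.size - tn
        sens = Fraction(tp, pos.size)
        spec = Fraction(tn, neg.size)
        rows.append(CutoffRow(
            threshold=float(t if positive_direction == "greater" else -t),
            sensitivity=float(sens) * 100.0,
            sens_ci=ci(tp, pos.size, level),
            specificity=float(spec) * 100.0,
            spec_ci=ci(tn, neg.size, level),
            likelihood_ratio=likelihood_ratio(sens, spec),
            tp=tp, fn=fn, tn=tn, fp=fp,
        ))
    return rows


def cutoff_table_frame(rows: list[CutoffRow]) -> pd.DataFrame:
    """Cutoff rows as a tidy DataFrame for CSV/markdown output."""
    return pd.DataFrame([{
        "threshold": r.threshold,
        "sensitivity_pct": r.sensitivity,
        "sens_ci_low": r.sens_ci[0],
        "sens_ci_high": r.sens_ci[1],
        "specificity_pct": r.specificity,
        "spec_ci_low": r.spec_ci[0],
        "spec_ci_high": r.spec_ci[1],
        "likelihood_ratio": r.likelihood_ratio,
        "tp": r.tp, "fn": r.fn, "tn": r.tn, "fp": r.fp,
    } for r in rows])


def delong_auc_ci(values, labels, level: float = 0.95
                  ) -> tuple[float, float, float]:
    """AUC with DeLong variance-based confidence interval.

    Returns ``(auc, lo, hi)``.  Uses the structural-component formulation:
    per-positive and per-negative placement values whose variances combine
    into the sampling variance of the empirical AUC.
    """
    values, labels = _validate_binary(values, labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives, and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = ss.norm.ppf(0.5 + level / 2.0)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)
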