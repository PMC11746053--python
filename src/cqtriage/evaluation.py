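"""Diagnostic performance statistics.

ROC AUC (mid-rank Mann–Whitney form) with DeLong confidence intervals,
sensitivity/specificity at a cutoff with exact Clopper–Pearson binomial
intervals, Mann–Whitney group comparisons with Bonferroni control, Spearman
rank correlation, and rounded group-summary percentage tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import DataError, UndefinedCorrelationError


@dataclass
class DiagnosticMetrics:
    auc: float | None
    auc_ci: tuple | None
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    tp: int
    fp: int
    tn: int
    fn: int
    contrast: str | None = None
    cutoff: float | None = None


@dataclass
class GroupTestResult:
    label: str
    u_statistic: float
    p_value: float
    bonferroni_threshold: float | None = None

    @property
    def significant(self) -> bool:
        if self.bonferroni_threshold is None:
            raise ValueError("no Bonferroni threshold attached")
        return self.p_value < self.bonferroni_threshold


@dataclass
class CorrelationResult:
    label: str
    spearman_rs: float
    n: int


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the mid-rank Mann–Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted one half; identical to the trapezoidal area
    under the empirical ROC curve.
    """
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(pos, neg):
    """DeLong placement-based variance of the empirical AUC."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa (mid-rank)
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95) -> tuple:
    """DeLong normal-approximation confidence interval for the AUC,
    clipped to [0, 1]."""
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise DataError("AUC CI requires at least 2 samples per class")
    auc = roc_auc(scores, labels)
    var = _delong_variance(pos, neg)
    if auc in (0.0, 1.0):
        warnings.warn("degenerate AUC; interval clipped", stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple:
    """Exact (beta-quantile) two-sided binomial interval, in percent."""
    if not 0 <= successes <= trials or trials < 1:
        raise DataError("require 0 ≤ successes ≤ trials, trials ≥ 1")
    alpha = 1.0 - level
    if successes == 0:
        lo = 0.0
    else:
        lo = stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1)
    if successes == trials:
        hi = 1.0
    else:
        hi = stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes)
    return (100.0 * lo, 100.0 * hi)


def sens_spec(
    scores,
    labels,
    cutoff: float = 0.0,
    level: float = 0.95,
    contrast: str | None = None,
    with_auc: bool = True,
) -> DiagnosticMetrics:
    """Sensitivity and specificity at a cutoff (score > cutoff calls
    positive), with Clopper–Pearson intervals, plus the ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _split(scores, labels)  # validates
    called = scores > cutoff
    pos = labels == 1
    tp = int((called & pos).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & ~pos).sum())
    fp = int((called & ~pos).sum())
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    auc = ci = None
    if with_auc:
        auc = roc_auc(scores, labels)
        if pos.sum() >= 2 and (~pos).sum() >= 2:
            ci = auc_ci(scores, labels, level)
    return DiagnosticMetrics(
        auc=auc,
        auc_ci=ci,
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(tp, tp + fn, level),
        specificity=spec,
        specificity_ci=clopper_pearson(tn, tn + fp, level),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        contrast=contrast,
        cutoff=cutoff,
    )


def mann_whitney(group_a, group_b, label: str = "") -> GroupTestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when both groups have ≤ 8 tie-free observations;
    otherwise the normal approximation with continuity and tie correction.
    Identical pooled values short-circuit to p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupTestResult(label, len(a) * len(b) / 2.0, 1.0)
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(label, float(res.statistic), float(res.pvalue))


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level alpha / m."""
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise DataError("n_comparisons must be ≥ 1")
    return alpha / n_comparisons


def spearman(x, y, label: str = "") -> CorrelationResult:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("spearman requires equal-length vectors of length ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant vector has no rank correlation")
    rs = stats.spearmanr(x, y).statistic
    return CorrelationResult(label, float(rs), len(x))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (2.65 -> 2.7), matching printed report style."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def group_summary(positives, totals, group_names=None):
    """Per-group and pooled positivity percentages, rounded half-up to 0.1.

    Returns a list of ``(name, positives, total, percent)`` rows with a
    final ``"pooled"`` row. Groups with zero total get percent None.
    """
    positives = [int(p) for p in positives]
    totals = [int(t) for t in totals]
    if len(positives) != len(totals):
        raise DataError("positives and totals must align")
    for p, t in zip(positives, totals):
        if not 0 <= p <= t:
            raise DataError(f"invalid counts: {p} positives of {t}")
    if group_names is None:
        group_names = [f"group{i + 1}" for i in range(len(totals))]
    rows = []
    for name, p, t in zip(group_names, positives, totals):
        pct = None if t == 0 else round_half_up(100.0 * p / t, 1)
        rows.append((name, p, t, pct))
    pooled_p, pooled_t = sum(positives), sum(totals)
    pooled = None if pooled_t == 0 else round_half_up(100.0 * pooled_p / pooled_t, 1)
    rows.append(("pooled", pooled_p, pooled_t, pooled))
    return rows
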