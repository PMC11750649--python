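"""Criterion-validity statistics: ROC with a KS-optimal cutoff, AUC
significance, the accuracy rate AR = 2*AUC - 1, and Spearman correlations.

The ROC is built explicitly from midpoint thresholds with the ">= threshold
classifies positive" rule: thresholds are the midpoints between distinct
sorted scores plus -inf/+inf sentinels, so tied scores collapse into a
single ROC step and the trapezoidal AUC equals the tie-corrected
Mann-Whitney concordant-pair fraction.  The operating cutoff is the
threshold maximizing the Kolmogorov-Smirnov metric sensitivity +
specificity - 1 (equivalently max |TPR - FPR|); ties are broken toward
higher sensitivity, then toward the lower threshold.

The AUC p-value tests AUC = 0.5 via the Mann-Whitney U statistic: exact
permutation when both classes have <= 10 observations, otherwise the normal
approximation with tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

#: class sizes up to which the exact permutation p-value is used
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and summary statistics for one metric vs one reference."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_p: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    accuracy_rate: float
    ks_statistic: float
    degenerate: bool = False  # all scores identical: cutoff is meaningless


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    constant_input: bool = False


def accuracy_rate(auc: float) -> float:
    """Chance-corrected accuracy rate AR = 2*AUC - 1."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc={auc} outside [0, 1]")
    return 2.0 * auc - 1.0


def _mann_whitney_u(scores: np.ndarray, labels: np.ndarray) -> tuple[float, int, int]:
    """U statistic for positives vs negatives via midranks (ties give 1/2)."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)  # midranks
    u = float(ranks[labels].sum() - n1 * (n1 + 1) / 2.0)
    return u, n1, n0


def auc_pvalue(scores, labels) -> float:
    """Two-sided p-value against AUC = 0.5.

    Exact permutation over all label assignments when both classes have at
    most ten observations; otherwise the tie-corrected Mann-Whitney normal
    approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 < 3 or n0 < 3:
        raise ValueError(f"need >= 3 observations per class, got {n1} positives / {n0} negatives")
    u_obs, _, _ = _mann_whitney_u(scores, labels)
    mu = n1 * n0 / 2.0

    if max(n1, n0) <= EXACT_PERMUTATION_MAX_N:
        ranks = stats.rankdata(scores)
        offset = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for pos_idx in combinations(range(scores.size), n1):
            u = ranks[list(pos_idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return count / total

    n = n1 + n0
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0  # all scores identical
    z = (u_obs - mu) / math.sqrt(sigma2)
    return float(2.0 * stats.norm.sf(abs(z)))


def roc_analysis(scores, labels) -> ROCResult:
    """Full ROC analysis of a metric against a binary reference.

    Parameters
    ----------
    scores : array-like
        Metric values; higher means more freezer-like.
    labels : array-like of bool
        Reference classification; freezer = positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0:
        raise ValueError("no positive (freezer) observations in labels")
    if n0 == 0:
        raise ValueError("no negative (non-freezer) observations in labels")

    distinct = np.unique(scores)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], midpoints, [np.inf]))

    pos = scores[labels]
    neg = scores[~labels]
    # score >= threshold -> classified positive
    sens = np.array([(pos >= th).mean() for th in thresholds])
    spec = np.array([(neg < th).mean() for th in thresholds])

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending FPR, then ascending TPR
    auc = float(np.trapezoid(sens[order], fpr[order]))
    auc = min(max(auc, 0.0), 1.0)

    ks = sens + spec - 1.0
    ks_max = float(ks.max())
    best = np.flatnonzero(np.isclose(ks, ks_max, atol=1e-12))
    # ties: prefer higher sensitivity, then lower threshold
    best = sorted(best, key=lambda i: (-sens[i], thresholds[i]))
    i_best = best[0]

    degenerate = distinct.size == 1
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_p=auc_pvalue(scores, labels) if min(n1, n0) >= 3 else float("nan"),
        cutoff=float(thresholds[i_best]),
        sens_at_cutoff=float(sens[i_best]),
        spec_at_cutoff=float(spec[i_best]),
        accuracy_rate=accuracy_rate(auc),
        ks_statistic=ks_max,
        degenerate=degenerate,
    )


def ks_optimal_cutoff(roc: ROCResult) -> float:
    """The threshold maximizing sensitivity + specificity - 1."""
    return roc.cutoff


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value.

    Constant input makes rho undefined; the result is flagged rather than
    silently NaN-propagated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs for a p-value, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=n, constant_input=True)
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=n)
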