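"""Empirical ROC curves, AUC, optimal cutoff, and the DeLong paired test.

Conventions: larger scores are more suspicious for mutation; a patient is
called positive when score >= threshold.  Candidate thresholds are the
unique observed scores plus sentinels above the maximum (nobody called
positive: sens 0, spec 1) and below the minimum (everybody positive:
sens 1, spec 0).  Tied scores share a single ROC vertex, so the trapezoid
area equals the Mann-Whitney statistic with ties counted one half.

The optimal operating point is the vertex closest to the top-left corner
of ROC space, i.e. minimizing d² = (1-sensitivity)² + (1-specificity)²;
ties on d² are broken toward higher specificity (fewer false positives).

Paired AUC comparison uses DeLong's structural-components estimate of
var(AUC_a - AUC_b) on the same patients, with a standard-normal z test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocCurve",
    "CutoffResult",
    "PairedAucResult",
    "DegenerateVarianceError",
    "roc_curve",
    "auc_mann_whitney",
    "auc_confidence_interval",
    "optimal_cutoff",
    "paired_auc_test",
]


class DegenerateVarianceError(RuntimeError):
    """DeLong variance is zero while the AUCs differ; no z test exists."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: vertices at all candidate thresholds.

    ``thresholds`` is decreasing in classification stringency order:
    +inf sentinel, unique scores descending, -inf sentinel, so sensitivity
    is non-decreasing and specificity non-increasing along the arrays.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(
            zip(
                self.thresholds.tolist(),
                self.sensitivity.tolist(),
                self.specificity.tolist(),
            )
        )


@dataclass(frozen=True)
class CutoffResult:
    """Closest-to-corner operating point and its distance criterion d²."""

    threshold: float
    sensitivity: float
    specificity: float
    d2: float


@dataclass(frozen=True)
class PairedAucResult:
    auc_a: float
    auc_b: float
    delta: float
    var_delta: float
    z: float
    p_value: float


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative label")
    return scores, labels, pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: P(case > control) + ½P(tie)."""
    scores, labels, pos, neg = _split(scores, labels)
    ranks = rankdata(scores)
    m = len(pos)
    u = ranks[labels == 1].sum() - m * (m + 1) / 2.0
    return float(u / (m * len(neg)))


def roc_curve(scores, labels) -> RocCurve:
    """Construct the empirical ROC curve of a score against binary truth."""
    scores, labels, pos, neg = _split(scores, labels)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq, [-np.inf]])
    sens = np.array([np.mean(pos >= t) for t in thresholds])
    spec = np.array([np.mean(neg < t) for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_mann_whitney(scores, labels),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def optimal_cutoff(curve: RocCurve) -> CutoffResult:
    """Vertex minimizing d² = (1-sens)² + (1-spec)².

    Equal d² (to within 1e-12) is resolved toward higher specificity;
    a residual tie is resolved toward the higher (stricter) threshold.
    """
    d2 = (1.0 - curve.sensitivity) ** 2 + (1.0 - curve.specificity) ** 2
    best = d2.min()
    tied = np.flatnonzero(d2 <= best + 1e-12)
    # among ties: max specificity, then max threshold; thresholds are stored
    # in descending order so the first qualifying index is the strictest
    spec_tied = curve.specificity[tied]
    tied = tied[spec_tied == spec_tied.max()]
    i = tied[0]
    return CutoffResult(
        threshold=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        d2=float(d2[i]),
    )


def _structural_components(scores, labels):
    """DeLong placement values V10 (per case) and V01 (per control)."""
    _, _, pos, neg = _split(scores, labels)
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def auc_confidence_interval(scores, labels, level: float = 0.95):
    """DeLong (asymptotic-normal) confidence interval for a single AUC."""
    v10, v01, auc = _structural_components(scores, labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def paired_auc_test(scores_a, scores_b, labels) -> PairedAucResult:
    """DeLong z test for the difference of two correlated AUCs.

    Both scores must be observed on the same patients (paired design).
    Zero estimated variance with a zero AUC difference returns p = 1 by
    convention; zero variance with a nonzero difference raises
    :class:`DegenerateVarianceError`.
    """
    a10, a01, auc_a = _structural_components(scores_a, labels)
    b10, b01, auc_b = _structural_components(scores_b, labels)
    m, n = len(a10), len(a01)
    s10 = np.cov(np.vstack([a10, b10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([a01, b01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        if abs(delta) < 1e-12:
            return PairedAucResult(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
        raise DegenerateVarianceError(
            "zero estimated variance with a nonzero AUC difference"
        )
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return PairedAucResult(auc_a, auc_b, float(delta), float(var), float(z), p)
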