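"""Logistic combination of IHC scores into a mutation probability.

The core idea: a mutation-specific antibody also stains some wild-type
tumors, and that nonspecific signal scales with the tumor's total EGFR
expression.  Feeding *both* the mutation-marker score and the total-EGFR
score into a binary logistic regression yields a predicted mutation
probability p̂ = logistic(β₀ + β·x) whose ROC curve dominates the raw
single-marker readout.  Each scoring scheme pairs a mutation feature
(intensity or quickscore) with an optional total-EGFR feature (none,
intensity, or quickscore), giving six schemes per target mutation.

Fitting is maximum likelihood via iteratively reweighted least squares
(Newton scoring with step halving).  Complete separation — a threshold on
one feature that classifies perfectly, common in small cohorts with a
near-perfect antibody — is detected and raised explicitly; a
Firth-penalized fit (Jeffreys-prior score correction) is available as a
fallback for separated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io import parse_genotype

__all__ = [
    "SchemeSpec",
    "CoefficientSet",
    "SeparationError",
    "ConfigurationError",
    "schemes_for_target",
    "build_features",
    "fit_logistic",
    "predict_probability",
]

TARGETS = ("L858R", "delE746-A750")
_TARGET_MARKER = {"L858R": "l858r", "delE746-A750": "del19"}
_TARGET_LABEL = {
    "L858R": lambda g: g.is_l858r,
    "delE746-A750": lambda g: g.is_e746_a750,
}
_FEATURE_WORD = {"intensity": "intensity", "qscore": "Q score"}


class SeparationError(RuntimeError):
    """The data are completely separated; the MLE does not exist."""


class ConfigurationError(KeyError):
    """The cohort lacks a column required by the requested scheme."""


@dataclass(frozen=True)
class SchemeSpec:
    """One row of the scoring-scheme grid.

    ``mutation_feature`` is how the mutation-specific antibody is
    quantified; ``total_egfr_feature`` is ``none`` for a single-marker
    scheme or the total-EGFR quantification for a combined scheme.
    """

    target: str
    mutation_feature: str
    total_egfr_feature: str = "none"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        if self.mutation_feature not in ("intensity", "qscore"):
            raise ValueError("mutation_feature must be 'intensity' or 'qscore'")
        if self.total_egfr_feature not in ("none", "intensity", "qscore"):
            raise ValueError(
                "total_egfr_feature must be 'none', 'intensity' or 'qscore'"
            )

    @property
    def name(self) -> str:
        base = f"{self.target} {_FEATURE_WORD[self.mutation_feature]}"
        if self.total_egfr_feature == "none":
            return base
        return f"{base} + total EGFR {_FEATURE_WORD[self.total_egfr_feature]}"

    @property
    def is_combined(self) -> bool:
        return self.total_egfr_feature != "none"


def schemes_for_target(target: str) -> list[SchemeSpec]:
    """The six scoring schemes for one target mutation, single-marker first."""
    out = [SchemeSpec(target, m) for m in ("intensity", "qscore")]
    out += [
        SchemeSpec(target, m, t)
        for m in ("intensity", "qscore")
        for t in ("intensity", "qscore")
    ]
    return out


def _feature_column(cohort, marker: str, kind: str) -> np.ndarray:
    icol, pcol = f"{marker}_intensity", f"{marker}_percent"
    for col in (icol,) if kind == "intensity" else (icol, pcol):
        if col not in cohort.columns:
            raise ConfigurationError(
                f"cohort lacks column {col!r} required by the scheme"
            )
    intensity = cohort[icol].to_numpy(dtype=float)
    if kind == "intensity":
        return intensity
    return intensity * cohort[pcol].to_numpy(dtype=float)


def build_features(cohort, scheme: SchemeSpec):
    """Feature matrix, binary label vector and feature names for a scheme.

    Labels come from the sequencing genotype: for the L858R target any
    genotype containing L858R counts (complex mutations included); for the
    E746-A750 target only exact E746-A750 deletions count.
    """
    marker = _TARGET_MARKER[scheme.target]
    cols = [_feature_column(cohort, marker, scheme.mutation_feature)]
    names = [f"{marker}_{scheme.mutation_feature}"]
    if scheme.total_egfr_feature != "none":
        cols.append(
            _feature_column(cohort, "total_egfr", scheme.total_egfr_feature)
        )
        names.append(f"total_egfr_{scheme.total_egfr_feature}")
    label_fn = _TARGET_LABEL[scheme.target]
    y = np.array(
        [label_fn(parse_genotype(g)) for g in cohort["genotype"]], dtype=int
    )
    return np.column_stack(cols), y, names


@dataclass
class CoefficientSet:
    """Fitted logistic coefficients with convergence diagnostics.

    ``std_errors`` and ``cov`` are Wald quantities from the observed
    information at the optimum, ordered (intercept, slopes...).
    """

    intercept: float
    slopes: np.ndarray
    converged: bool
    deviance: float
    n_iter: int
    std_errors: np.ndarray = field(default=None, repr=False)
    cov: np.ndarray = field(default=None, repr=False)
    method: str = "mle"

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.slopes])


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def _check_threshold_separation(X: np.ndarray, y: np.ndarray) -> None:
    pos, neg = X[y == 1], X[y == 0]
    for j in range(X.shape[1]):
        if pos[:, j].min() > neg[:, j].max() or pos[:, j].max() < neg[:, j].min():
            raise SeparationError(
                f"feature column {j} completely separates cases from controls; "
                "the maximum-likelihood estimate does not exist "
                "(consider firth=True)"
            )


def fit_logistic(
    features,
    labels,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
) -> CoefficientSet:
    """Maximum-likelihood logistic regression via IRLS.

    Deterministic given the input (no randomness, order-invariant up to
    floating-point associativity of the normal equations).  Raises
    :class:`SeparationError` on completely separated data unless
    ``firth=True``, in which case the Firth bias-reduced estimate (which
    exists under separation) is returned with ``method="firth"``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels have different lengths")
    if not (np.all((y == 0) | (y == 1))):
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant feature column; drop it or fit intercept-only")
    if not firth:
        _check_threshold_separation(X, y)

    Xd = np.column_stack([np.ones_like(y), X])
    beta = np.zeros(Xd.shape[1])
    dev = _deviance(y, expit(Xd @ beta))
    converged = False
    n_iter = 0
    info = np.eye(Xd.shape[1])
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        XtW = Xd.T * w
        info = XtW @ Xd
        resid = y - mu
        if firth:
            # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
            h = w * np.einsum("ij,ji->i", Xd, np.linalg.solve(info, Xd.T))
            resid = resid + h * (0.5 - mu)
        try:
            step = np.linalg.solve(info, Xd.T @ resid)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix during IRLS; data may be "
                "separated or collinear"
            ) from exc
        # step halving keeps the deviance monotone non-increasing
        new_beta = beta + step
        new_dev = _deviance(y, expit(Xd @ new_beta))
        if not firth:
            halves = 0
            while new_dev > dev + 1e-10 and halves < 25:
                step /= 2.0
                new_beta = beta + step
                new_dev = _deviance(y, expit(Xd @ new_beta))
                halves += 1
        beta = new_beta
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    if not firth and dev < 1e-6:
        # perfect fit reachable only under separation in >1 dimension
        raise SeparationError(
            "fit drove the deviance to zero: the data are completely "
            "separated (consider firth=True)"
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full_like(info, np.nan)
        se = np.full(Xd.shape[1], np.nan)
    return CoefficientSet(
        intercept=float(beta[0]),
        slopes=beta[1:].copy(),
        converged=converged,
        deviance=dev,
        n_iter=n_iter,
        std_errors=se,
        cov=cov,
        method="firth" if firth else "mle",
    )


def predict_probability(coefs: CoefficientSet, features) -> np.ndarray:
    """Predicted mutation probability p̂ = logistic(β₀ + β·x) per patient."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(coefs.slopes):
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match "
            f"{len(coefs.slopes)} fitted slope(s)"
        )
    return expit(coefs.intercept + X @ coefs.slopes)
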