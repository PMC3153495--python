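"""Diagnostic accuracy against sequencing truth, plus categorical tests.

Metrics are reported on the percent scale.  Two rounding conventions are
exposed for the likelihood ratios:

``exact``
    LR+ = sens/(1-spec) and LR- = (1-sens)/spec from full-precision
    sensitivity and specificity.
``printed``
    Sensitivity/specificity are first rounded to one decimal percent and
    the likelihood ratios are formed from the *rounded* values, then
    rounded to three decimals.  This is how diagnostic tables produced
    from rounded operating points are typically computed (e.g. a 2x2 of
    38/23/5/77 gives LR+ 3.843 under printed rounding but 3.842 exactly),
    so both conventions are first-class.

The chi-square test is Pearson's without continuity correction; Fisher's
exact test is the two-sided hypergeometric sum.  Both wrap scipy.  Wilson
score intervals for proportions are provided as an extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "confusion_from_calls",
    "diagnostic_metrics",
    "pearson_chi2",
    "fisher_exact",
    "wilson_ci",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of classifier call vs sequencing truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """[[tp, fp], [fn, tn]] — calls in rows, truth in columns."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def confusion_from_calls(calls, truth) -> ConfusionTable:
    """Tabulate binary classifier calls against binary truth."""
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape or calls.ndim != 1:
        raise ValueError("calls and truth must be equal-length 1-D vectors")
    return ConfusionTable(
        tp=int(np.sum((calls == 1) & (truth == 1))),
        fp=int(np.sum((calls == 1) & (truth == 0))),
        fn=int(np.sum((calls == 0) & (truth == 1))),
        tn=int(np.sum((calls == 0) & (truth == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    """Diagnostic metrics in percent; likelihood ratios as positive reals.

    Metrics whose denominator is zero are NaN, except LR+ with perfect
    specificity which is +inf; ``undefined`` and ``infinite`` are explicit
    flags naming any such metric.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_plus: float
    lr_minus: float
    rounding: str
    undefined: tuple = ()
    infinite: tuple = ()


def _safe_pct(num: int, den: int):
    return (100.0 * num / den, None) if den > 0 else (math.nan, "undefined")


def diagnostic_metrics(table: ConfusionTable, rounding: str = "exact") -> MetricSet:
    """Sensitivity, specificity, PPV, NPV, accuracy and likelihood ratios.

    ``rounding`` is ``"exact"`` or ``"printed"`` (see module docstring).
    """
    if rounding not in ("exact", "printed"):
        raise ValueError("rounding must be 'exact' or 'printed'")
    undefined, infinite = [], []
    sens, flag = _safe_pct(table.tp, table.tp + table.fn)
    if flag:
        undefined.append("sensitivity")
    spec, flag = _safe_pct(table.tn, table.tn + table.fp)
    if flag:
        undefined.append("specificity")
    ppv, flag = _safe_pct(table.tp, table.tp + table.fp)
    if flag:
        undefined.append("ppv")
    npv, flag = _safe_pct(table.tn, table.tn + table.fn)
    if flag:
        undefined.append("npv")
    accuracy = 100.0 * (table.tp + table.tn) / table.total

    if rounding == "printed":
        sens, spec, ppv, npv, accuracy = (
            round(v, 1) for v in (sens, spec, ppv, npv, accuracy)
        )

    if math.isnan(sens) or math.isnan(spec):
        lr_plus = lr_minus = math.nan
        undefined += ["lr_plus", "lr_minus"]
    else:
        if spec >= 100.0:
            lr_plus = math.inf
            infinite.append("lr_plus")
        else:
            lr_plus = sens / (100.0 - spec)
        if spec <= 0.0:
            lr_minus = math.nan
            undefined.append("lr_minus")
        else:
            lr_minus = (100.0 - sens) / spec
        if rounding == "printed":
            if math.isfinite(lr_plus):
                lr_plus = round(lr_plus, 3)
            if math.isfinite(lr_minus):
                lr_minus = round(lr_minus, 3)
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
        rounding=rounding,
        undefined=tuple(undefined),
        infinite=tuple(infinite),
    )


def _as_2x2(table) -> np.ndarray:
    t = table.as_array() if isinstance(table, ConfusionTable) else np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of nonnegative counts")
    return t


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, 1 df."""
    t = _as_2x2(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: expected counts are undefined")
    res = stats.chi2_contingency(t, correction=False)
    return float(res[0]), float(res[1])


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: hypergeometric tables as or less probable."""
    t = _as_2x2(table)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def expected_counts_below(table, threshold: float = 5.0) -> bool:
    """True when any expected cell count falls below ``threshold``.

    The conventional trigger for preferring Fisher's exact test over the
    chi-square approximation on small tables.
    """
    t = _as_2x2(table).astype(float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return bool(np.any(expected < threshold))


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (fractional scale)."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)
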