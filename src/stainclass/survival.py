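"""Progression-free-survival analysis by IHC status.

Kaplan-Meier product-limit estimation and the two-group log-rank test are
backed by lifelines; Cox proportional-hazards regression is backed by
statsmodels PHReg, which supports both the Efron (default; appropriate for
month-resolution times with many ties) and Breslow approximations to the
partial likelihood under tied event times.

The median survival convention is the smallest time t with S(t) <= 0.5;
if the curve never reaches 0.5 the median is undefined and flagged.
Median follow-up uses the reverse Kaplan-Meier convention (censoring and
event indicators swapped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "KmResult",
    "CoxConvergenceError",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "median_followup",
]


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass(frozen=True)
class KmResult:
    """Kaplan-Meier step function.

    ``times``/``survival`` are the step-function knots (S is right-
    continuous and equals ``survival[i]`` on [times[i], times[i+1])).
    ``median`` is NaN when ``median_defined`` is False.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_defined: bool
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray:
        """S(t), vectorized; S(t) = 1 for t before the first knot."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.size > 1 else float(out[0])


def _clean(durations, events):
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("durations and events must be equal-length 1-D vectors")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("durations must be finite and positive")
    if not np.all((e == 0) | (e == 1)):
        raise ValueError("events must be binary 0/1")
    return t, e


def km_estimate(durations, events) -> KmResult:
    """Product-limit survival estimate with the <=0.5 median convention."""
    t, e = _clean(durations, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    defined = np.isfinite(median)
    return KmResult(
        times=times,
        survival=surv,
        median=median if defined else float("nan"),
        median_defined=bool(defined),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(durations, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p), 1 df."""
    t, e = _clean(durations, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match durations in length")
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    for lev in levels:
        if e[g == lev].sum() == 0:
            raise ValueError(f"group {lev!r} has no observed events")
    mask = g == levels[0]
    res = _lifelines_logrank(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


def median_followup(durations, events) -> float:
    """Median follow-up by reverse Kaplan-Meier (events treated as censored)."""
    t, e = _clean(durations, events)
    return km_estimate(t, 1 - e).median


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "pfs_months",
    event_col: str = "pfs_event",
    ties: str = "efron",
    level: float = 0.95,
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    Returns columns ``coef``, ``hr``, ``hr_ci_low``, ``hr_ci_high``,
    ``p`` (Wald).  Covariates must be numeric (encode categories as 0/1
    indicators upstream).  Raises :class:`CoxConvergenceError` on
    non-convergence or monotone likelihood (runaway coefficients).
    """
    import statsmodels.api as sm

    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _clean(data[duration_col], data[event_col])
    if e.sum() == 0:
        raise ValueError("no observed events")
    X = data[covariates].astype(float)
    if np.any(X.nunique() <= 1):
        constant = list(X.columns[X.nunique() <= 1])
        raise ValueError(f"constant covariate(s): {constant}")
    model = sm.PHReg(t, X, status=e, ties=ties)
    try:
        res = model.fit(disp=False)
    except Exception as exc:  # statsmodels raises various numeric errors
        raise CoxConvergenceError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 20):
        raise CoxConvergenceError(
            "runaway coefficient: likely monotone partial likelihood"
        )
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "coef": params,
            "hr": np.exp(params),
            "hr_ci_low": np.exp(params - z * bse),
            "hr_ci_high": np.exp(params + z * bse),
            "p": np.asarray(res.pvalues, dtype=float),
        },
        index=covariates,
    )
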