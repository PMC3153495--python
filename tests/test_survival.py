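"""Kaplan-Meier, log-rank and Cox PFS analysis."""

import numpy as np
import pandas as pd
import pytest

from stainclass import cox_fit, km_estimate, logrank_test, median_followup
from stainclass.survival import CoxConvergenceError


def test_km_two_events_no_censoring():
    km = km_estimate([1.0, 2.0], [1, 1])
    assert km.survival_at(1.0) == pytest.approx(0.5)
    assert km.survival_at(2.0) == pytest.approx(0.0)
    assert km.median == 1.0 and km.median_defined


def test_km_without_censoring_equals_one_minus_ecdf(rng):
    t = rng.exponential(5.0, 300)
    km = km_estimate(t, np.ones(300, int))
    grid = np.quantile(t, [0.1, 0.4, 0.7, 0.9])
    for g in grid:
        ecdf = np.mean(t <= g)
        assert km.survival_at(g) == pytest.approx(1 - ecdf, abs=1e-12)


def test_km_median_undefined_when_curve_stays_high():
    km = km_estimate([1, 2, 3, 4, 5], [1, 0, 0, 0, 0])
    assert not km.median_defined and np.isnan(km.median)


def test_km_curve_monotone_right_continuous(rng):
    t = rng.exponential(10.0, 500)
    e = rng.integers(0, 2, 500)
    e[:5] = 1
    km = km_estimate(t, e)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert km.survival_at(1e-9) == pytest.approx(1.0)


def test_km_recovers_exponential_median(rng):
    # exponential with median 12.0, ~20% uniform censoring
    t = rng.exponential(12.0 / np.log(2), 5000)
    tau = 48.0
    c = rng.uniform(0, tau, 5000)
    km = km_estimate(np.minimum(t, c), (t <= c).astype(int))
    assert abs(km.median - 12.0) < 0.7


def test_logrank_identical_groups_null():
    t = np.tile([1.0, 2.0, 3.0, 4.0], 2)
    e = np.ones(8, int)
    g = np.repeat([0, 1], 4)
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_requires_two_groups_with_events():
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])


def test_logrank_invariant_to_group_relabeling(rng):
    t = rng.exponential(8.0, 80)
    e = np.ones(80, int)
    g = rng.integers(0, 2, 80)
    g[:2] = [0, 1]
    chi2_a, p_a = logrank_test(t, e, g)
    chi2_b, p_b = logrank_test(t, e, 1 - g)
    assert chi2_a == pytest.approx(chi2_b)
    assert p_a == pytest.approx(p_b)


def test_logrank_agrees_with_permutation_oracle(rng):
    t = rng.exponential([6.0] * 15 + [12.0] * 15)
    e = (rng.random(30) < 0.8).astype(int)
    e[:2] = 1
    g = np.repeat([0, 1], 15)
    chi2_obs, p_asym = logrank_test(t, e, g)
    reps = 5000
    exceed = 0
    for _ in range(reps):
        gp = rng.permutation(g)
        chi2_p, _ = logrank_test(t, e, gp)
        exceed += chi2_p >= chi2_obs - 1e-12
    p_perm = exceed / reps
    assert abs(p_perm - p_asym) < 0.02


def test_cox_duplication_invariance(rng):
    # duplicating every sample creates exact ties; the Breslow partial
    # likelihood is exactly invariant, Efron's tie correction only nearly so
    n = 120
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(np.where(g == 1, 5.0, 10.0))
    df = pd.DataFrame({"pfs_months": t, "pfs_event": 1, "g": g})
    dup = pd.concat([df, df], ignore_index=True)
    hr_b = cox_fit(df, ["g"], ties="breslow").loc["g", "hr"]
    hr_b_dup = cox_fit(dup, ["g"], ties="breslow").loc["g", "hr"]
    assert hr_b_dup == pytest.approx(hr_b, rel=1e-6)
    hr_e = cox_fit(df, ["g"], ties="efron").loc["g", "hr"]
    hr_e_dup = cox_fit(dup, ["g"], ties="efron").loc["g", "hr"]
    assert hr_e_dup == pytest.approx(hr_e, rel=0.02)


def test_cox_time_rescaling_invariance(rng):
    n = 150
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(np.where(g == 1, 4.0, 9.0))
    e = (rng.random(n) < 0.85).astype(int)
    df = pd.DataFrame({"pfs_months": t, "pfs_event": e, "g": g})
    hr_months = cox_fit(df, ["g"]).loc["g", "hr"]
    df_days = df.assign(pfs_months=df.pfs_months * 30.4)
    hr_days = cox_fit(df_days, ["g"]).loc["g", "hr"]
    assert hr_days == pytest.approx(hr_months, rel=1e-6)


def test_cox_agrees_with_lifelines(rng):
    from lifelines import CoxPHFitter

    n = 200
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x1 - 0.3 * x2)))
    c = rng.uniform(0, 30, n)
    df = pd.DataFrame(
        {
            "pfs_months": np.round(np.minimum(t, c), 1) + 0.05,
            "pfs_event": (t <= c).astype(int),
            "x1": x1,
            "x2": x2,
        }
    )
    ours = cox_fit(df, ["x1", "x2"])  # Efron ties, statsmodels backend
    ref = CoxPHFitter().fit(df, "pfs_months", "pfs_event")
    np.testing.assert_allclose(
        ours["coef"].to_numpy(),
        ref.params_[["x1", "x2"]].to_numpy(),
        rtol=1e-4,
    )


def test_cox_breslow_ties_flag(rng):
    n = 150
    g = rng.integers(0, 2, n).astype(float)
    t = np.ceil(rng.exponential(np.where(g == 1, 4.0, 9.0)))  # month ties
    df = pd.DataFrame({"pfs_months": t, "pfs_event": 1, "g": g})
    hr_e = cox_fit(df, ["g"], ties="efron").loc["g", "hr"]
    hr_b = cox_fit(df, ["g"], ties="breslow").loc["g", "hr"]
    assert hr_e != hr_b  # tie corrections genuinely differ with many ties
    assert abs(np.log(hr_e) - np.log(hr_b)) < 0.3


def test_cox_coverage_of_null_covariate():
    rng = np.random.default_rng(99)
    covered = 0
    n_sims = 300
    for _ in range(n_sims):
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(8.0, n)
        e = (rng.random(n) < 0.85).astype(int)
        if e.sum() == 0:
            e[0] = 1
        df = pd.DataFrame({"pfs_months": t, "pfs_event": e, "x": x})
        row = cox_fit(df, ["x"]).loc["x"]
        covered += row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]
    assert covered / n_sims >= 0.93


def test_cox_rejects_constant_covariate():
    df = pd.DataFrame(
        {"pfs_months": [1.0, 2, 3, 4], "pfs_event": [1, 1, 1, 1], "x": 1.0}
    )
    with pytest.raises(ValueError, match="constant"):
        cox_fit(df, ["x"])


def test_cox_monotone_likelihood_raises():
    # the binary covariate perfectly orders event times: monotone likelihood
    df = pd.DataFrame(
        {
            "pfs_months": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "pfs_event": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )
    with pytest.raises(CoxConvergenceError):
        cox_fit(df, ["x"])


def test_median_followup_reverse_km():
    # all events: no censoring distribution information -> undefined median
    t = [2.0, 4.0, 6.0, 8.0]
    assert np.isnan(median_followup(t, [1, 1, 1, 1]))
    m = median_followup(t, [0, 0, 0, 0])
    assert m == 4.0  # reverse KM equals KM of the censoring times
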