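"""Feature construction and IRLS logistic fitting."""

import numpy as np
import pytest
from scipy.special import expit

from stainclass import (
    SchemeSpec,
    SeparationError,
    build_features,
    fit_logistic,
    predict_probability,
    schemes_for_target,
)
from stainclass.roc import auc_mann_whitney

from conftest import toy_cohort


def test_scheme_grid_matches_scoring_table_layout():
    for target in ("L858R", "delE746-A750"):
        schemes = schemes_for_target(target)
        assert len(schemes) == 6
        assert sum(not s.is_combined for s in schemes) == 2
        assert sum(s.is_combined for s in schemes) == 4
    assert (
        SchemeSpec("L858R", "qscore", "qscore").name
        == "L858R Q score + total EGFR Q score"
    )


def test_build_features_qscore_columns():
    cohort = toy_cohort(
        [
            {"genotype": "L858R", "l858r_intensity": 3, "l858r_percent": 80.0,
             "total_egfr_intensity": 2, "total_egfr_percent": 50.0},
            {"genotype": "wild", "l858r_intensity": 1, "l858r_percent": 20.0,
             "total_egfr_intensity": 1, "total_egfr_percent": 30.0},
            {"genotype": "delE746-A750", "l858r_intensity": 0,
             "total_egfr_intensity": 3, "total_egfr_percent": 90.0},
        ]
    )
    X, y, names = build_features(cohort, SchemeSpec("L858R", "qscore", "qscore"))
    assert X.shape == (3, 2)
    np.testing.assert_allclose(X[:, 0], [240.0, 20.0, 0.0])
    np.testing.assert_allclose(X[:, 1], [100.0, 30.0, 270.0])
    np.testing.assert_array_equal(y, [1, 0, 0])

    X1, y1, _ = build_features(cohort, SchemeSpec("L858R", "intensity"))
    assert X1.shape == (3, 1)
    np.testing.assert_allclose(X1[:, 0], [3, 1, 0])


def test_l858r_label_includes_complex_genotypes():
    cohort = toy_cohort(
        [{"genotype": g} for g in
         ("L858R", "L858R+V834L", "L858R+T790M", "delE746-A750", "wild")]
    )
    _, y, _ = build_features(cohort, SchemeSpec("L858R", "intensity"))
    assert y.sum() == 3
    _, y_del, _ = build_features(cohort, SchemeSpec("delE746-A750", "intensity"))
    assert y_del.sum() == 1


def test_del_label_excludes_other_exon19_deletions():
    cohort = toy_cohort(
        [{"genotype": g} for g in ("delE746-A750", "delL747-T751", "wild")]
    )
    _, y, _ = build_features(cohort, SchemeSpec("delE746-A750", "intensity"))
    np.testing.assert_array_equal(y, [1, 0, 0])


def test_missing_stain_column_is_configuration_error(default_cohort):
    broken = default_cohort.drop(columns=["total_egfr_percent"])
    with pytest.raises(KeyError, match="total_egfr_percent"):
        build_features(broken, SchemeSpec("L858R", "qscore", "qscore"))


def test_no_signal_fit_recovers_prevalence(rng):
    x = rng.normal(size=2000)
    y = rng.random(2000) < 0.3  # independent of x
    fit = fit_logistic(x, y.astype(int))
    assert fit.converged
    assert abs(fit.slopes[0]) < 0.15
    prevalence_logit = np.log(y.mean() / (1 - y.mean()))
    assert abs(fit.intercept - prevalence_logit) < 0.15


def test_parameter_recovery_within_wald_cis():
    rng = np.random.default_rng(3)
    q = rng.uniform(0, 300, 5000)
    y = (rng.random(5000) < expit(-1 + 0.02 * q)).astype(int)
    fit = fit_logistic(q, y)
    lo = fit.params - 1.96 * fit.std_errors
    hi = fit.params + 1.96 * fit.std_errors
    assert lo[0] <= -1.0 <= hi[0]
    assert lo[1] <= 0.02 <= hi[1]
    # known-parameter closed form at Q = 50: logistic(-1 + 0.02*50) = 0.5
    p50 = predict_probability(fit, np.array([50.0]))
    assert abs(p50[0] - 0.5) < 0.03


def test_matches_statsmodels_mle():
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    X = rng.normal(size=(300, 2)) * [50, 30]
    y = (rng.random(300) < expit(0.3 + 0.01 * X[:, 0] - 0.02 * X[:, 1])).astype(int)
    ours = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=False)
    np.testing.assert_allclose(ours.params, ref.params, rtol=1e-6)
    np.testing.assert_allclose(ours.std_errors, ref.bse, rtol=1e-4)


def test_perfect_separation_raises():
    x = np.array([3.0, 3.0, 3.0, 0.0, 0.0, 0.0])
    y = np.array([1, 1, 1, 0, 0, 0])
    with pytest.raises(SeparationError):
        fit_logistic(x, y)


def test_firth_fallback_fits_separated_data():
    x = np.array([3.0, 3.0, 3.0, 0.0, 0.0, 0.0])
    y = np.array([1, 1, 1, 0, 0, 0])
    fit = fit_logistic(x, y, firth=True)
    assert fit.method == "firth"
    assert np.all(np.isfinite(fit.params))
    assert fit.slopes[0] > 0


def test_constant_feature_rejected():
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(np.ones(10), np.array([0, 1] * 5))


def test_refit_invariant_to_row_permutation(default_cohort, rng):
    X, y, _ = build_features(default_cohort, SchemeSpec("L858R", "qscore", "qscore"))
    fit = fit_logistic(X, y)
    perm = rng.permutation(len(y))
    fit_p = fit_logistic(X[perm], y[perm])
    np.testing.assert_allclose(fit.params, fit_p.params, atol=1e-8)


def test_nested_model_deviance_ordering(default_cohort):
    X2, y, _ = build_features(default_cohort, SchemeSpec("L858R", "qscore", "qscore"))
    fit2 = fit_logistic(X2, y)
    fit1 = fit_logistic(X2[:, :1], y)
    assert fit2.deviance <= fit1.deviance + 1e-9


def test_single_feature_probability_preserves_auc(default_cohort):
    # the logistic transform is monotone, so p-hat and the raw feature rank
    # patients identically
    X, y, _ = build_features(default_cohort, SchemeSpec("L858R", "qscore"))
    fit = fit_logistic(X, y)
    p = predict_probability(fit, X)
    assert auc_mann_whitney(p, y) == pytest.approx(auc_mann_whitney(X.ravel(), y), abs=1e-12)


def test_predict_probability_edge_values():
    from stainclass import CoefficientSet

    zero = CoefficientSet(0.0, np.array([0.0]), True, 0.0, 1)
    np.testing.assert_allclose(predict_probability(zero, np.array([3.0, -7.0])), 0.5)
    unit = CoefficientSet(0.0, np.array([1.0]), True, 0.0, 1)
    assert predict_probability(unit, np.array([0.0]))[0] == 0.5
    with pytest.raises(ValueError, match="dimension"):
        predict_probability(unit, np.ones((4, 2)))
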