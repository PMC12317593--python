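import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from casemix import (
    Cohort,
    FittedCPM,
    develop_model,
    fit_weighted_logistic,
    predict_risk,
)
from casemix.exceptions import ConfigurationError, DegenerateOutcomeError

from conftest import random_cohort


def sm_logit(cohort, mask=None):
    mask = np.ones(cohort.N, bool) if mask is None else mask
    A = sm.add_constant(cohort.X[mask])
    return sm.GLM(cohort.Y[mask], A, family=sm.families.Binomial()).fit()


class TestWeightedFit:
    def test_unit_weights_reduce_to_ordinary_mle(self, small_cohort):
        fit = fit_weighted_logistic(small_cohort)
        ref = sm_logit(small_cohort)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-8
        )

    def test_integer_weights_equal_row_duplication(self, rng):
        c = random_cohort(rng, n=150, k=2)
        w = rng.integers(1, 4, c.N).astype(float)
        fit = fit_weighted_logistic(c, weights=w)
        idx = np.repeat(np.arange(c.N), w.astype(int))
        dup = Cohort(c.X[idx], c.Y[idx], c.R[idx], c.predictor_names)
        ref = fit_weighted_logistic(dup)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients],
            np.r_[ref.intercept, ref.coefficients],
            atol=1e-8,
        )

    def test_zero_weights_exclude_rows(self, rng):
        c = random_cohort(rng, n=200, k=2)
        w = np.ones(c.N)
        w[:60] = 0.0
        fit = fit_weighted_logistic(c, weights=w)
        ref = sm_logit(c, mask=w > 0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-8
        )

    def test_single_class_after_weighting_is_degenerate(self, rng):
        c = random_cohort(rng, n=100, k=2)
        w = np.where(c.Y == 1, 0.0, 1.0)
        with pytest.raises(DegenerateOutcomeError):
            fit_weighted_logistic(c, weights=w)

    def test_weighted_score_equation_holds_at_optimum(self, rng):
        c = random_cohort(rng, n=500, k=3)
        w = rng.uniform(0.2, 1.0, c.N)
        fit = fit_weighted_logistic(c, weights=w, tol=1e-12)
        p = fit.predict_risk(c.X)
        assert abs(np.sum(w * (c.Y - p))) < 1e-8

    def test_scale_equivariance(self, rng):
        c = random_cohort(rng, n=300, k=2)
        fit = fit_weighted_logistic(c, tol=1e-12)
        X2 = c.X.copy()
        X2[:, 0] /= 10.0
        c2 = Cohort(X2, c.Y, c.R, c.predictor_names)
        fit2 = fit_weighted_logistic(c2, tol=1e-12)
        np.testing.assert_allclose(fit2.coefficients[0], fit.coefficients[0] * 10, atol=1e-6)
        np.testing.assert_allclose(fit2.predict_risk(X2), fit.predict_risk(c.X), atol=1e-8)

    def test_weighted_loglik_matches_definition(self, rng):
        c = random_cohort(rng, n=120, k=2)
        w = rng.uniform(0.5, 2.0, c.N)
        fit = fit_weighted_logistic(c, weights=w)
        p = fit.predict_risk(c.X)
        ll = np.sum(w * (c.Y * np.log(p) + (1 - c.Y) * np.log(1 - p)))
        np.testing.assert_allclose(fit.loglik, ll, rtol=1e-10)


class TestDevelopModel:
    def test_target_only_with_dummy_is_invalid(self, small_cohort):
        with pytest.raises(ConfigurationError):
            develop_model(small_cohort, strategy="target_only", weight_regime=None,
                          include_dummy_R=True)

    def test_target_only_with_weights_is_invalid(self, small_cohort):
        with pytest.raises(ConfigurationError):
            develop_model(small_cohort, strategy="target_only", weight_regime="capped")

    def test_unknown_strategy_is_invalid(self, small_cohort):
        with pytest.raises(ConfigurationError):
            develop_model(small_cohort, strategy="magic")

    def test_target_only_equals_fit_on_target_rows(self, rng):
        c = random_cohort(rng, n=400, k=2)
        fit = develop_model(c, strategy="target_only", weight_regime=None)
        ref = sm_logit(c, mask=c.R == 0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-8
        )
        assert fit.dummy_R_coefficient is None

    def test_all_unweighted_dummy_shifts_lp_by_delta(self, rng):
        c = random_cohort(rng, n=400, k=2)
        fit = develop_model(c, strategy="all_unweighted", weight_regime=None,
                            include_dummy_R=True)
        lp_t = fit.linear_predictor(c.X, as_target=True)
        lp_s = fit.linear_predictor(c.X, as_target=False)
        np.testing.assert_allclose(lp_s - lp_t, fit.dummy_R_coefficient, atol=1e-12)


class TestPredictRisk:
    def test_null_model_predicts_half(self):
        m = FittedCPM(0.0, [0.0, 0.0], ("a", "b"))
        np.testing.assert_allclose(predict_risk(m, np.zeros((5, 2))), 0.5)

    def test_hand_case(self):
        m = FittedCPM(-2.0, [1.0], ("x",))
        np.testing.assert_allclose(predict_risk(m, np.array([[2.0]]))[0], 0.5)

    def test_dimension_mismatch_raises(self):
        m = FittedCPM(0.0, [1.0], ("x",))
        from casemix.exceptions import SchemaError

        with pytest.raises(SchemaError):
            predict_risk(m, np.zeros((3, 2)))

    def test_json_round_trip(self, rng):
        c = random_cohort(rng)
        fit = develop_model(c, strategy="all_unweighted", weight_regime=None)
        back = FittedCPM.from_json(fit.to_json())
        np.testing.assert_allclose(back.coefficients, fit.coefficients)
        assert back.strategy == "all_unweighted"


def test_membership_weighting_reduces_target_region_bias(rng):
    """Under a partial covariate shift with a misspecified linear model, the
    weighted fit's coefficients sit closer to the target-population best
    linear approximation than the all-data unweighted fit's, on average."""
    from casemix.simulate import GeneratorConfig, ShiftSpec, calibrate_intercept, generate_cohort
    import dataclasses

    shift = ShiftSpec("partial", "age", (18.0, 80.0), (57.0, 103.0))
    cfg = GeneratorConfig(s=1500, n=400, shift=shift)
    cfg = dataclasses.replace(cfg, gamma0=calibrate_intercept(cfg, 0.05))
    # target-population reference: best linear fit at very large n
    big = dataclasses.replace(cfg, s=0, n=120_000)
    ref = develop_model(generate_cohort(big, seed=9), strategy="target_only",
                        weight_regime=None)
    ref_coef = np.r_[ref.intercept, ref.coefficients]

    bias_w, bias_u = [], []
    for seed in range(200):
        c = generate_cohort(cfg, seed=seed)
        if len(np.unique(c.target.Y)) < 2:
            continue
        mw = develop_model(c, strategy="membership_weighted", weight_regime="capped")
        mu = develop_model(c, strategy="all_unweighted", weight_regime=None)
        bias_w.append(np.r_[mw.intercept, mw.coefficients] - ref_coef)
        bias_u.append(np.r_[mu.intercept, mu.coefficients] - ref_coef)
    mean_abs_w = np.abs(np.mean(bias_w, axis=0))
    mean_abs_u = np.abs(np.mean(bias_u, axis=0))
    # compare overall coefficient bias magnitude
    assert np.linalg.norm(mean_abs_w) <= np.linalg.norm(mean_abs_u)
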