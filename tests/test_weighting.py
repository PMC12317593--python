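import numpy as np
import pytest
from scipy.special import expit, logit

from casemix import (
    Cohort,
    MembershipModel,
    effective_sample_size,
    fit_membership_model,
    propensity,
    weights_capped,
    weights_raw,
    weights_scaled,
)
from casemix.exceptions import DegenerateLabelsError, QuasiSeparationWarning

from conftest import random_cohort


class TestMembershipModel:
    def test_constant_predictors_give_intercept_only_mle(self):
        X = np.ones((100, 1))
        R = np.r_[np.ones(30, int), np.zeros(70, int)]
        c = Cohort(X, np.r_[np.ones(50, int), np.zeros(50, int)], R, ("x",))
        m = fit_membership_model(c)
        ps = propensity(m, X)
        np.testing.assert_allclose(ps, 0.3, atol=1e-6)

    def test_perfect_separation_warns(self):
        x = np.r_[np.linspace(2, 3, 30), np.linspace(-3, -2, 30)]
        R = np.r_[np.ones(30, int), np.zeros(30, int)]
        c = Cohort(x[:, None], np.tile([0, 1], 30), R, ("x",))
        with pytest.warns(QuasiSeparationWarning):
            m = fit_membership_model(c, ridge=0.0)
        assert m.separation_suspected

    def test_single_class_membership_is_degenerate(self, rng):
        c = random_cohort(rng, source_frac=0.0)
        with pytest.raises(DegenerateLabelsError):
            fit_membership_model(c)

    def test_fitted_likelihood_beats_coarse_grid(self, rng):
        """MLE sanity: the fitted (alpha, beta) dominates a grid around it."""
        c = random_cohort(rng, n=50, k=1, source_frac=0.4)
        m = fit_membership_model(c)

        def ll(a, b):
            ps = np.clip(expit(a + b * c.X[:, 0]), 1e-12, 1 - 1e-12)
            return np.sum(c.R * np.log(ps) + (1 - c.R) * np.log(1 - ps))

        best = ll(m.intercept, m.coefficients[0])
        grid = [
            ll(m.intercept + da, m.coefficients[0] + db)
            for da in np.linspace(-0.5, 0.5, 11)
            for db in np.linspace(-0.5, 0.5, 11)
        ]
        assert best >= max(grid) - 1e-9

    def test_ridge_shrinks_separated_coefficients(self):
        x = np.r_[np.linspace(2, 3, 30), np.linspace(-3, -2, 30)]
        R = np.r_[np.ones(30, int), np.zeros(30, int)]
        c = Cohort(x[:, None], np.tile([0, 1], 30), R, ("x",))
        with pytest.warns(QuasiSeparationWarning):
            m0 = fit_membership_model(c, ridge=0.0)
        m1 = fit_membership_model(c, ridge=1.0)
        assert abs(m1.coefficients[0]) < abs(m0.coefficients[0])

    def test_json_round_trip(self, rng):
        c = random_cohort(rng)
        m = fit_membership_model(c)
        back = MembershipModel.from_json(m.to_json())
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        assert back.predictor_names == m.predictor_names


class TestPropensity:
    def test_zero_model_gives_half(self):
        m = MembershipModel(0.0, [0.0], ("x",))
        np.testing.assert_allclose(propensity(m, np.array([[3.0], [-2.0]])), 0.5)

    def test_intercept_only_gives_marginal(self):
        m = MembershipModel(float(logit(0.3)), [0.0], ("x",))
        np.testing.assert_allclose(propensity(m, np.array([[1.0]])), 0.3, atol=1e-12)

    def test_hand_computed_single_row(self):
        m = MembershipModel(-1.0, [2.0], ("x",))
        np.testing.assert_allclose(
            propensity(m, np.array([[1.0]]))[0], 1 / (1 + np.exp(-1)), atol=1e-12
        )


class TestWeightRegimes:
    def test_raw_identity_when_no_shift(self):
        ps = np.full(4, 0.5)
        R = np.array([1, 1, 0, 0])
        wv = weights_raw(ps, R)
        np.testing.assert_allclose(wv.w, 1.0)

    def test_raw_arithmetic_uncapped(self):
        wv = weights_raw(np.array([0.2]), np.array([1]), s=50, n=100)
        np.testing.assert_allclose(wv.w[0], 2.0)

    def test_boundary_propensity_gives_vanishing_weight(self):
        wv = weights_raw(np.array([1 - 1e-12]), np.array([1]), s=10, n=10)
        assert wv.w[0] < 1e-11

    def test_capped_arithmetic(self):
        wv = weights_capped(np.array([0.8, 0.2]), np.array([1, 1]), s=100, n=50)
        np.testing.assert_allclose(wv.w[0], 0.5)  # min((0.2/0.8)*2, 1)
        wv2 = weights_capped(np.array([0.2]), np.array([1]), s=50, n=100)
        np.testing.assert_allclose(wv2.w[0], 1.0)  # cap binds at min(2, 1)

    def test_capped_no_shift_identity(self):
        R = np.r_[np.ones(30, int), np.zeros(70, int)]
        wv = weights_capped(np.full(100, 0.3), R)
        np.testing.assert_allclose(wv.w, 1.0)

    def test_scaled_sum_equals_s_when_triggered(self):
        ps = np.array([0.6, 0.25, 0.2])  # raw: [0.5, 1.5*2... ] with s=n=3
        R = np.array([1, 1, 1])
        wv = weights_scaled(ps, R, s=3, n=3)
        assert wv.scaling_factor is not None
        np.testing.assert_allclose(wv.w.sum(), 3.0, atol=1e-12)

    def test_scaled_untriggered_passes_raw_through(self):
        ps, R = np.array([0.9, 0.85]), np.array([1, 1])
        raw = weights_raw(ps, R, s=2, n=2)
        scaled = weights_scaled(ps, R, s=2, n=2)
        assert scaled.scaling_factor is None
        np.testing.assert_allclose(scaled.w, raw.w)

    def test_unit_weights_are_fixed_point(self):
        ps, R = np.full(3, 0.5), np.ones(3, int)
        wv = weights_scaled(ps, R, s=3, n=3)
        np.testing.assert_allclose(wv.w, 1.0)
        assert wv.scaling_factor is None

    def test_target_rows_always_weight_one(self, rng):
        ps = rng.uniform(0.05, 0.95, 50)
        R = rng.integers(0, 2, 50)
        R[:2] = [0, 1]
        for fn in (weights_raw, weights_capped, weights_scaled):
            np.testing.assert_array_equal(fn(ps, R).w[R == 0], 1.0)

    def test_weights_strictly_decrease_in_propensity(self):
        ps = np.linspace(0.05, 0.95, 40)
        R = np.ones(40, int)
        raw = weights_raw(ps, R, s=10, n=10).w
        assert (np.diff(raw) < 0).all()
        capped = weights_capped(ps, R, s=10, n=10).w
        assert (np.diff(capped) <= 0).all()


class TestEffectiveSampleSize:
    def test_capped_all_ones(self):
        R = np.r_[np.ones(100, int), np.zeros(50, int)]
        wv = weights_capped(np.full(150, 100 / 150), R)
        assert effective_sample_size(wv) == (pytest.approx(100), pytest.approx(150))

    def test_zero_source_weights(self):
        R = np.array([1, 1, 0, 0, 0])
        wv = weights_raw(np.full(5, 1 - 1e-12), R)
        es, et = effective_sample_size(wv)
        assert es == pytest.approx(0, abs=1e-10) and et == pytest.approx(3, abs=1e-10)

    def test_mixed_weight_arithmetic(self):
        from casemix import WeightVector

        wv = WeightVector(np.r_[0.5, 0.25, np.ones(10)], np.r_[1, 1, np.zeros(10)].astype(int), "capped")
        assert effective_sample_size(wv) == (0.75, 10.75)

    def test_ess_ordering_capped_vs_raw_vs_scaled(self, rng):
        ps = rng.uniform(0.1, 0.9, 300)
        R = rng.integers(0, 2, 300)
        R[:2] = [0, 1]
        raw, capped, scaled = (fn(ps, R) for fn in (weights_raw, weights_capped, weights_scaled))
        assert capped.ess_source <= raw.ess_source + 1e-12
        assert scaled.ess_source <= R.sum() + 1e-9


def test_no_shift_propensity_and_weights_approach_one(rng):
    """When source and target share a distribution, PS -> s/N and w -> 1."""
    c = random_cohort(rng, n=20_000, k=3, source_frac=0.5)
    m = fit_membership_model(c)
    ps = propensity(m, c.X)
    np.testing.assert_allclose(ps.mean(), c.s / c.N, atol=0.01)
    wv = weights_capped(ps, c.R)
    src_w = wv.w[c.R == 1]
    assert src_w.min() > 0.85 and (src_w <= 1).all()
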