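"""Mathematics of the stretched exponential model and the omega solver."""

import math

import numpy as np
import pytest

from lifespan_limit import (
    E_INV,
    InsufficientDataError,
    ModelError,
    NoCharacteristicAgeError,
    SurvivalCurve,
    UndefinedHazardError,
    estimate_alpha,
    extract_beta,
    fit_beta_quadratic,
    fit_gompertz,
    gamma_at,
    mortality_rate,
    rectangular_beta_approx,
    solve_omega,
    survival_at,
)
from conftest import curve_from_fit, make_fit, random_valid_fits


class TestSurvivalAt:
    def test_characteristic_age_gives_e_inverse(self):
        for fit in random_valid_fits(5, seed=3):
            assert survival_at(fit, fit.alpha) == pytest.approx(E_INV, abs=1e-15)

    def test_constant_beta_one_reduces_to_simple_exponential(self):
        fit = make_fit(alpha=80.0, b0=1.0, b1=0.0, b2=0.0)
        assert survival_at(fit, 160.0) == pytest.approx(math.exp(-2.0), abs=1e-15)

    def test_direct_arithmetic(self):
        fit = make_fit(alpha=88.0, b0=12.0, b1=0.0, b2=0.0)
        # exp(-(100/88)**12), computed independently
        assert survival_at(fit, 100.0) == pytest.approx(0.009689730666444393, abs=1e-15)

    def test_rejects_nonpositive_age(self):
        with pytest.raises(ModelError):
            survival_at(make_fit(), 0.0)


class TestMortalityRate:
    def test_constant_hazard_of_simple_exponential(self):
        alpha = 50.0
        ages = np.arange(0.0, 111.0)
        curve = SurvivalCurve(ages=ages, s=np.exp(-ages / alpha))
        mu = mortality_rate(curve, 60.0)
        # forward difference of exp(-x/alpha) is exactly 1/alpha in log space
        assert mu == pytest.approx(1.0 / alpha, abs=1e-12)

    def test_hand_value_on_grid(self):
        curve = SurvivalCurve(ages=np.array([49.0, 50.0, 51.0]),
                              s=np.array([1.0, 0.9, 0.8]))
        assert mortality_rate(curve, 50.0) == pytest.approx(0.11778303565638339, abs=1e-14)

    def test_zero_survival_is_undefined(self):
        curve = SurvivalCurve(ages=np.array([49.0, 50.0, 51.0]),
                              s=np.array([1.0, 0.5, 0.0]))
        with pytest.raises(UndefinedHazardError):
            mortality_rate(curve, 50.0)

    def test_analytic_matches_forward_difference(self):
        fit = make_fit()
        x = 95.0
        analytic = mortality_rate(fit, x)
        h = 1e-6
        numeric = -(math.log(survival_at(fit, x + h)) - math.log(survival_at(fit, x))) / h
        assert analytic == pytest.approx(numeric, rel=1e-6)


class TestEstimateAlpha:
    def test_hand_interpolation(self):
        ages = np.array([0.0, 89.0, 90.0])
        s = np.array([1.0, 0.40, 0.36])
        assert estimate_alpha(SurvivalCurve(ages=ages, s=s)) == pytest.approx(
            89.80301397071395, abs=1e-12
        )

    def test_round_trip_recovery_on_fine_grid(self):
        fit = make_fit(alpha=85.0, b1=0.19, b2=-0.00135)
        curve = curve_from_fit(fit, age_max=110, step=0.1)
        assert abs(estimate_alpha(curve) - 85.0) <= 0.1

    def test_no_crossing_is_an_error(self):
        curve = SurvivalCurve(ages=np.arange(3.0), s=np.array([1.0, 0.8, 0.6]))
        with pytest.raises(NoCharacteristicAgeError):
            estimate_alpha(curve)


class TestExtractBeta:
    def test_simple_exponential_gives_beta_one(self):
        alpha = 70.0
        ages = np.arange(0.0, 111.0)
        curve = SurvivalCurve(ages=ages, s=np.exp(-ages / alpha))
        profile = extract_beta(curve, alpha)
        assert profile.valid_mask.sum() > 50
        assert np.allclose(profile.beta[profile.valid_mask], 1.0, atol=1e-10)

    def test_age_equal_alpha_masked(self):
        alpha = 70.0
        ages = np.arange(0.0, 111.0)
        curve = SurvivalCurve(ages=ages, s=np.exp(-ages / alpha))
        profile = extract_beta(curve, alpha)
        assert not profile.valid_mask[70]
        assert np.all(np.isfinite(profile.beta))  # masked entries are 0, not NaN

    def test_quadratic_round_trip(self):
        fit = make_fit()
        curve = curve_from_fit(fit)
        profile = extract_beta(curve, fit.alpha)
        expected = fit.beta(profile.ages[profile.valid_mask])
        assert np.allclose(profile.beta[profile.valid_mask], expected, atol=1e-10)


class TestFitBetaQuadratic:
    def test_exact_quadratic_recovered(self):
        fit = make_fit()
        profile = extract_beta(curve_from_fit(fit), fit.alpha)
        refit = fit_beta_quadratic(profile, (100.0, 110.0))
        assert refit.b0 == pytest.approx(fit.b0, abs=1e-8)
        assert refit.b1 == pytest.approx(fit.b1, abs=1e-8)
        assert refit.b2 == pytest.approx(fit.b2, abs=1e-8)
        assert refit.n_points == 10
        assert refit.residual_rms < 1e-10

    def test_too_few_points_is_an_error(self):
        fit = make_fit()
        profile = extract_beta(curve_from_fit(fit), fit.alpha)
        with pytest.raises(InsufficientDataError, match="extreme-age"):
            fit_beta_quadratic(profile, (108.0, 110.0))

    def test_noisy_recovery_within_three_standard_errors(self):
        fit = make_fit()
        profile = extract_beta(curve_from_fit(fit), fit.alpha)
        rng = np.random.default_rng(42)
        sigma = 0.05
        noisy = profile.beta.copy()
        noisy[profile.valid_mask] += rng.normal(0, sigma, profile.valid_mask.sum())
        profile.beta = noisy
        refit = fit_beta_quadratic(profile, (100.0, 110.0))
        x = np.arange(100.0, 110.0)
        X = np.vander(x, 3, increasing=True)
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        for est, true, s in zip((refit.b0, refit.b1, refit.b2),
                                (fit.b0, fit.b1, fit.b2), se):
            assert abs(est - true) <= 3 * s


class TestGamma:
    def test_constant_beta_gives_zero_everywhere(self):
        fit = make_fit(b0=5.0, b1=0.0, b2=0.0)
        assert gamma_at(fit, 50.0) == 0.0
        assert gamma_at(fit, 150.0) == 0.0

    def test_zero_at_alpha(self):
        assert gamma_at(make_fit(), 88.0) == 0.0

    def test_hand_arithmetic(self):
        # window below 60 keeps beta positive for this steeply falling exponent
        fit = make_fit(alpha=88.0, b0=30.0, b1=-0.5, b2=0.0, window=(40.0, 55.0))
        # -110 * ln(110/88) * (-0.5), computed by hand
        assert gamma_at(fit, 110.0) == pytest.approx(12.272895322281537, abs=1e-12)


class TestSolveOmega:
    def test_constant_beta_has_no_finite_root(self):
        fit = make_fit(b0=8.0, b1=0.0, b2=0.0)
        est = solve_omega(fit, 200.0)
        assert not est.is_finite
        assert math.isnan(est.omega)

    def test_root_matches_dense_grid_argmin(self):
        fit = make_fit(alpha=88.0, b0=30.0, b1=-0.18, b2=0.0)
        est = solve_omega(fit, 200.0)
        xs = np.arange(0.001, 200.0, 0.001)
        brute = xs[np.argmin(survival_at(fit, xs))]
        assert est.is_finite
        assert abs(est.omega - brute) <= 0.001

    def test_survival_decreases_before_omega_and_rises_after(self):
        for fit in random_valid_fits(5, seed=9):
            est = solve_omega(fit, 200.0)
            assert est.is_finite
            eps = 0.5
            om = est.omega
            assert survival_at(fit, om - 2 * eps) > survival_at(fit, om - eps)
            assert survival_at(fit, om + eps) <= survival_at(fit, om + 2 * eps)

    def test_residual_within_tolerance(self):
        for fit in random_valid_fits(5, seed=1):
            est = solve_omega(fit, 200.0)
            assert est.is_finite and est.omega > fit.alpha
            assert abs(fit.beta(est.omega) - gamma_at(fit, est.omega)) <= 1e-4

    def test_bound_below_alpha_rejected(self):
        with pytest.raises(ModelError, match="search_bound"):
            solve_omega(make_fit(), 80.0)


class TestFitGompertz:
    @staticmethod
    def gompertz_curve(a, b, age_max=110):
        ages = np.arange(0.0, age_max + 1)
        s = np.exp(-(a / b) * np.expm1(b * ages))
        return SurvivalCurve(ages=ages, s=s)

    def test_parameters_recovered_exactly(self):
        a, b = 1e-5, 0.11
        fit = fit_gompertz(self.gompertz_curve(a, b), (40.0, 100.0))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)

    def test_constant_hazard_gives_zero_slope(self):
        ages = np.arange(0.0, 111.0)
        curve = SurvivalCurve(ages=ages, s=np.exp(-0.01 * ages))
        fit = fit_gompertz(curve, (40.0, 100.0))
        assert abs(fit.b) < 1e-10
        assert fit.a == pytest.approx(0.01, rel=1e-8)

    def test_zero_survival_window_is_an_error(self):
        ages = np.arange(0.0, 111.0)
        s = np.where(ages < 50, np.exp(-0.05 * ages), 0.0)
        s[0] = 1.0
        curve = SurvivalCurve(ages=ages, s=s)
        with pytest.raises(InsufficientDataError):
            fit_gompertz(curve, (60.0, 100.0))

    def test_diverges_from_stretched_model_at_extreme_ages(self):
        """A log-linear hazard fitted at adult ages tracks the rectangular
        curve in-window but diverges (here: overshoots) past age 100."""
        fit = make_fit()
        curve = curve_from_fit(fit)
        gomp = fit_gompertz(curve, (40.0, 90.0))
        in_window = gomp.hazard(65.0) / mortality_rate(fit, 65.0)
        at_extreme = gomp.hazard(105.0) / mortality_rate(fit, 105.0)
        assert 0.5 < in_window < 2.0
        assert at_extreme > 2.0 or at_extreme < 0.5


def test_rectangular_heuristic_is_exposed_but_small():
    # with x in plain years the heuristic sits far below fitted exponents
    assert rectangular_beta_approx(90.0) == pytest.approx(7 / math.log(90.0))
    assert rectangular_beta_approx(90.0) < 2.0
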