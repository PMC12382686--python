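"""Constitutive closures: porosity, fractal dimension, retention,
conductivity, and the grain-size-curve fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from soilcolumn.hydraulics import (
    GrainSizeCurve,
    InvalidSoilError,
    SoilHydraulicModel,
    bulk_density_from_porosity,
    effective_saturation,
    fit_grain_size_curve,
    grain_size_cdf,
    hydraulic_conductivity,
    moisture_content,
    porosity_from_bulk_density,
    solve_fractal_dimension,
    specific_capacity,
    suction_from_saturation,
)

M, N, PSI_D, KS = 0.18609, 3.1784, 92.8674, 0.9481


@pytest.fixture(scope="module")
def model():
    return SoilHydraulicModel(m=M, n=N, psi_d=PSI_D, Ks=KS, theta_s=0.4906, porosity=0.4906)


class TestPorosity:
    @pytest.mark.parametrize(
        "rho_a, rho_s, expected",
        [(1.35, 2.65, 0.4906), (0.0, 2.65, 1.0), (2.65, 2.65, 0.0)],
    )
    def test_values(self, rho_a, rho_s, expected):
        assert porosity_from_bulk_density(rho_a, rho_s) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("rho_a, rho_s", [(-1.0, 2.65), (1.0, 0.0), (3.0, 2.65)])
    def test_invalid(self, rho_a, rho_s):
        with pytest.raises(InvalidSoilError):
            porosity_from_bulk_density(rho_a, rho_s)

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_round_trip_with_algebraic_inverse(self, phi):
        assert porosity_from_bulk_density(bulk_density_from_porosity(phi)) == pytest.approx(
            phi, abs=1e-12
        )


class TestFractalDimension:
    def test_phi_half_closed_form(self):
        # at phi = 1/2 the equation reduces to x^2 + x - 1 = 0 in x = 0.5^s
        x = (np.sqrt(5.0) - 1.0) / 2.0
        expected = -np.log2(x)
        assert solve_fractal_dimension(0.5) == pytest.approx(expected, abs=1e-10)

    def test_table_porosity_root(self):
        # the defining equation is asserted, not the printed rounded value
        s = solve_fractal_dimension(0.4906)
        assert s == pytest.approx(0.692, abs=5e-4)
        assert abs((1 - 0.4906) ** s + 0.4906 ** (2 * s) - 1) < 1e-10

    @pytest.mark.parametrize("phi", np.arange(0.1, 0.95, 0.1))
    def test_agrees_with_bisection_oracle(self, phi):
        oracle = brentq(
            lambda s: (1 - phi) ** s + phi ** (2 * s) - 1, 1e-3, 1 - 1e-3, xtol=1e-14
        )
        s = solve_fractal_dimension(phi)
        assert s == pytest.approx(oracle, abs=1e-8)
        assert abs((1 - phi) ** s + phi ** (2 * s) - 1) < 1e-10

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.2])
    def test_invalid_porosity(self, phi):
        with pytest.raises(InvalidSoilError):
            solve_fractal_dimension(phi)


class TestRetentionCurve:
    def test_saturated_limit(self, model):
        assert effective_saturation(0.0, model) == 1.0
        assert effective_saturation(-3.5, model) == 1.0  # ponded

    def test_characteristic_pressure(self, model):
        assert effective_saturation(PSI_D, model) == pytest.approx(2.0 ** (-M), rel=1e-12)
        assert effective_saturation(PSI_D, model) == pytest.approx(0.8790, abs=5e-5)

    def test_dry_limit(self, model):
        # m is small, so the tail decays slowly: Theta ~ (psi/psi_d)^(-m n)
        assert effective_saturation(1e9, model) < 1e-3
        assert effective_saturation(1e12, model) < effective_saturation(1e9, model)

    @given(st.floats(min_value=0.1, max_value=5e3), st.floats(min_value=1.01, max_value=1e4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_suction(self, model, psi, factor):
        assert effective_saturation(psi * factor, model) < effective_saturation(psi, model)

    def test_inverse_round_trip(self, model):
        # near saturation the inversion loses digits to cancellation in
        # Theta^(-1/m) - 1, so the tolerance is loose at the wet end
        psi = np.array([20.0, 100.0, 500.0])
        se = effective_saturation(psi, model)
        np.testing.assert_allclose(suction_from_saturation(se, model), psi, rtol=1e-6)


class TestSpecificCapacity:
    def test_zero_on_saturated_plateau(self, model):
        assert specific_capacity(0.0, model) == 0.0
        assert specific_capacity(-2.0, model) == 0.0

    def test_matches_central_difference(self, model):
        h = 1e-4
        psi = 50.0
        numeric = (moisture_content(psi - h, model) - moisture_content(psi + h, model)) / (2 * h)
        assert abs(specific_capacity(psi, model) - numeric) < 1e-8

    def test_non_negative_everywhere(self, model):
        psi = np.geomspace(1e-3, 1e5, 200)
        assert np.all(specific_capacity(psi, model) >= 0.0)


class TestConductivityCurve:
    def test_saturated_equals_Ks(self, model):
        assert hydraulic_conductivity(1.0, model) == KS

    def test_dry_limit_zero(self, model):
        assert hydraulic_conductivity(0.0, model) == 0.0

    def test_strictly_increasing(self, model):
        se = np.linspace(0.05, 1.0, 40)
        K = hydraulic_conductivity(se, model)
        assert np.all(np.diff(K) > 0)
        assert hydraulic_conductivity(0.5, model) < hydraulic_conductivity(0.9, model)

    def test_alternative_reading_differs(self, model):
        k1 = hydraulic_conductivity(0.5, model, form="fractal")
        k2 = hydraulic_conductivity(0.5, model, form="fractal-alt")
        assert k1 != k2
        assert hydraulic_conductivity(1.0, model, form="fractal-alt") == KS

    def test_invalid_sm_rejected(self):
        # s/n combination pushing sm out of (0,1) must be rejected at build time
        with pytest.raises(InvalidSoilError):
            SoilHydraulicModel(m=M, n=1.2, psi_d=PSI_D, Ks=KS, theta_s=0.4906,
                              porosity=0.4906, s=0.7)


class TestModelInvariants:
    def test_sm_always_consistent_with_s_and_n(self, model):
        assert model.sm == 1.0 - 2.0 * model.s / model.n

    def test_moisture_ordering_enforced(self):
        with pytest.raises(InvalidSoilError):
            SoilHydraulicModel(m=M, n=N, psi_d=PSI_D, Ks=KS, theta_s=0.6, porosity=0.5)


class TestGrainSizeFit:
    TRUTH = dict(Dd=1136.6942, m=0.18609, n=3.1784)

    def _curve(self, s, noise=None, rng=None):
        d = np.geomspace(2.0, 2e4, 20)
        F = grain_size_cdf(d, s=s, **self.TRUTH)
        if noise:
            F = np.clip(F + rng.normal(0, noise, F.shape), 0, 1)
            F = np.maximum.accumulate(F)
        return GrainSizeCurve(d, F)

    def test_noise_free_recovery(self):
        s = 0.6923
        fit = fit_grain_size_curve(self._curve(s), s)
        assert fit.converged
        assert fit.rmse < 1e-6
        for key, truth in self.TRUTH.items():
            assert fit.estimates[key] == pytest.approx(truth, rel=1e-2)

    def test_noisy_rmse_near_noise_level(self, rng):
        s = 0.6923
        sigma = 0.01
        fit = fit_grain_size_curve(self._curve(s, noise=sigma, rng=rng), s)
        assert 0.3 * sigma < fit.rmse < 3.0 * sigma

    def test_cdf_limits(self):
        s = 0.6923
        assert grain_size_cdf(1e12, s=s, **self.TRUTH) == pytest.approx(1.0, abs=1e-6)
        assert grain_size_cdf(1e-9, s=s, **self.TRUTH) == pytest.approx(0.0, abs=1e-6)

    def test_rejects_too_few_points(self):
        curve = GrainSizeCurve([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])
        with pytest.raises(InvalidSoilError):
            fit_grain_size_curve(curve, 0.69)


class TestGrainSizeCurveValidation:
    def test_rejects_non_monotone(self):
        with pytest.raises(InvalidSoilError):
            GrainSizeCurve([1.0, 2.0, 3.0, 4.0], [0.1, 0.5, 0.4, 0.9])

    def test_rejects_out_of_range(self):
        with pytest.raises(InvalidSoilError):
            GrainSizeCurve([1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 0.9, 1.2])
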