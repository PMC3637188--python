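"""Piecewise-linear roll-off model, its error metrics and channel gains."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from cibeam import (
    ArrayConfig,
    ExtrapolationWarning,
    LinearizedModel,
    average_error,
    channel_gains,
    endpoint_response,
    error_report,
    find_turning_weight,
    linearized_response,
    normalization_coefficient,
    normalized_error,
    relative_error,
)

from conftest import complex_oracle

PHI = 2 * np.pi * 6000 * 0.01 / 340  # endpoint phase for the default geometry


class TestTurningWeight:
    def test_closed_form_equals_brute_force(self, array):
        """argmin over beta of the exact endpoint response, grid step 1e-4."""
        grid = np.arange(0.0, 1.0001, 1e-4)
        endpoint = np.sqrt(1 + grid**2 - 2 * grid * np.cos(PHI))
        brute = grid[np.argmin(endpoint)]
        assert find_turning_weight(array) == pytest.approx(brute, abs=1e-4)

    def test_default_geometry_rounds_to_045(self, array):
        assert round(find_turning_weight(array), 2) == 0.45

    def test_zero_band_limit_clamps_to_one(self, array):
        assert find_turning_weight(array, f_max=0.0) == 1.0

    def test_cardioid_delay_clamps_to_zero(self, array):
        assert find_turning_weight(array, tau=array.transit_delay) == 0.0


class TestEndpointModel:
    def test_unit_at_beta_zero(self, model):
        assert endpoint_response(0.0, model) == 1.0

    def test_turning_endpoint_matches_exact_oracle(self, model, array):
        want = complex_oracle(array.d, array.c, 0.45, 0.0, 0.0, 6000.0)
        assert endpoint_response(0.45, model) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(0.8952, abs=5e-4)

    def test_beta_one_endpoint_is_2sin(self, model):
        assert endpoint_response(1.0, model) == pytest.approx(2 * np.sin(PHI / 2), rel=1e-12)

    def test_out_of_range_weight_rejected(self, model):
        with pytest.raises(ValueError):
            endpoint_response(1.5, model)


class TestLinearizedResponse:
    def test_exact_at_both_endpoints(self, model):
        """The line interpolates (0, |1-beta|) and (f_max, endpoint) exactly."""
        for beta in np.arange(0.0, 1.0001, 0.05):
            assert linearized_response(beta, 0.0, model) == pytest.approx(
                1 - beta, abs=1e-12
            )
            assert linearized_response(beta, 6000.0, model) == pytest.approx(
                endpoint_response(beta, model), rel=1e-12
            )

    def test_printed_slope_coefficients_recovered(self, model):
        """Recomputing the slopes from H2, H3 reproduces the published numeric
        coefficients 1.279e-4, 2.145e-4, 3.896e-5 within 0.5% relative."""
        coef = model.slope_coefficients()
        assert coef["low_beta"] == pytest.approx(1.279e-4, rel=5e-3)
        assert coef["high_beta"] == pytest.approx(2.145e-4, rel=5e-3)
        assert coef["high_const"] == pytest.approx(3.896e-5, rel=5e-3)

    def test_published_coefficient_values(self, model):
        # H_eva(0.2, 3000) = 0.8 + 1.279e-4 * 0.2 * 3000 from the numeric form
        assert linearized_response(0.2, 3000.0, model) == pytest.approx(0.8767, abs=1e-3)
        # high-branch slope at beta=1 times 6000 ~ the endpoint response
        assert linearized_response(1.0, 6000.0, model) == pytest.approx(1.053, abs=1e-3)

    def test_large_weight_reduced_by_reciprocity(self, model):
        f = np.array([500.0, 2000.0, 5000.0])
        np.testing.assert_allclose(
            model.evaluate(2.0, f), 2.0 * model.evaluate(0.5, f), rtol=1e-12
        )

    def test_extrapolation_flagged(self, model):
        with pytest.warns(ExtrapolationWarning):
            linearized_response(0.5, 6276.0, model)
        with pytest.raises(ValueError):
            model.evaluate(0.5, 6276.0, extrapolate="raise")

    def test_negative_weight_rejected(self, model):
        with pytest.raises(ValueError):
            linearized_response(-0.1, 100.0, model)


class TestRelativeError:
    def test_zero_for_beta_zero(self, model):
        np.testing.assert_allclose(
            relative_error(0.0, np.linspace(10, 6000, 20), model), 0.0, atol=1e-12
        )

    def test_undefined_at_exact_null(self, model):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0, model)
        assert np.isnan(relative_error(1.0, 0.0, model, on_zero="nan"))

    def test_grid_extremes_within_printed_band(self, model):
        """Max relative error in (0, 40]% and min in [-10, 0)% on the
        standard beta (0.02) x f (50 Hz) grid."""
        betas = np.round(np.arange(0.02, 1.0001, 0.02), 10)
        freqs = np.arange(50.0, 6001.0, 50.0)
        surface = np.array([relative_error(b, freqs, model) for b in betas])
        assert 0.0 < surface.max() <= 40.0
        assert -10.0 <= surface.min() < 0.0


class TestNormalizationCoefficient:
    def test_unity_for_beta_zero(self, model):
        assert normalization_coefficient(0.0, model) == pytest.approx(1.0, abs=1e-14)

    def test_matches_integral_oracle_at_beta_one(self, model):
        """G(1) against closed-form numeric integration of both energies."""
        h3 = 2 * np.sin(PHI / 2)
        num, _ = quad(lambda f: (h3 * f / 6000.0) ** 2, 0.0, 6000.0)
        den, _ = quad(lambda f: 4 * np.sin(np.pi * f * 0.01 / 340) ** 2, 0.0, 6000.0)
        assert normalization_coefficient(1.0, model, n_points=5000) == pytest.approx(
            np.sqrt(num / den), rel=1e-4
        )

    def test_converges_in_n(self, model):
        for beta in np.arange(0.0, 1.0001, 0.1):
            g500 = normalization_coefficient(beta, model, n_points=500)
            g5000 = normalization_coefficient(beta, model, n_points=5000)
            assert abs(g500 - g5000) < 1e-3


class TestNormalizedAndAverageError:
    def test_zero_everywhere_for_beta_zero(self, model):
        f = np.linspace(10, 6000, 25)
        np.testing.assert_allclose(normalized_error(0.0, f, model=model), 0.0, atol=1e-10)
        assert average_error(0.0, model) == pytest.approx(0.0, abs=1e-10)

    def test_grid_extremes_within_printed_band(self, model):
        betas = np.round(np.arange(0.02, 1.0001, 0.02), 10)
        freqs = np.arange(50.0, 6001.0, 50.0)
        surface = np.array([normalized_error(b, freqs, model=model) for b in betas])
        assert surface.max() <= 40.0
        assert surface.min() >= -10.0

    @pytest.mark.parametrize("tau_factor", [0.0, 0.342, 1.0])
    def test_average_error_below_seven_percent(self, array, tau_factor):
        """Average error stays in the published 0-7% band for the dipolar,
        supercardioid and cardioid delays."""
        model = LinearizedModel.from_array(array, tau=tau_factor * array.transit_delay)
        for beta in np.round(np.arange(0.0, 1.0001, 0.02), 10):
            assert abs(average_error(beta, model)) <= 7.0


class TestErrorReport:
    def test_shapes_and_zero_row(self, model):
        rep = error_report(model, betas=[0.0, 0.5], freqs=[100.0, 1000.0, 5000.0])
        assert rep.relative_errors.shape == (2, 3)
        assert rep.normalized_errors.shape == (2, 3)
        np.testing.assert_allclose(rep.relative_errors[0], 0.0, atol=1e-12)
        assert rep.G_values[0] == pytest.approx(1.0, abs=1e-14)
        assert rep.average_errors[0] == pytest.approx(0.0, abs=1e-10)

    def test_rejects_out_of_range_weights(self, model):
        with pytest.raises(ValueError):
            error_report(model, betas=[1.5])


class TestChannelGains:
    def test_reference_gain_is_one(self, bank, model):
        for mode in ("linearized", "ideal"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                g = channel_gains(1.0, bank, mode=mode, model=model)
            assert g.reference_channel_index == 3  # 1005 Hz channel
            assert g.gains[3] == pytest.approx(1.0, abs=1e-15)

    def test_ideal_gain_matches_exact_ratio(self, bank, model, array):
        g = channel_gains(1.0, bank, mode="ideal", model=model)
        want = (2 * np.sin(np.pi * 1005 * 0.01 / 340)
                / (2 * np.sin(np.pi * 274 * 0.01 / 340)))
        assert g.gains[0] == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(3.66, abs=0.01)

    def test_gain_sign_structure_for_dipolar(self, bank, model):
        """Low channels are amplified, channels above the reference attenuated."""
        g = channel_gains(1.0, bank, mode="ideal", model=model)
        assert np.all(g.gains[:3] > 1.0)
        assert np.all(g.gains[4:] < 1.0)

    def test_linearized_tracks_ideal(self, bank, model):
        """Linearized gains track the ideal ones: tightly at the common
        beta = 1 operating point, and within the bound implied by the
        relative-error surface (<= 40%) across the weight grid."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            lin1 = channel_gains(1.0, bank, mode="linearized", model=model)
        np.testing.assert_allclose(
            lin1.gains, channel_gains(1.0, bank, mode="ideal", model=model).gains,
            rtol=0.10)
        for beta in np.round(np.arange(0.1, 1.0001, 0.1), 10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                lin = channel_gains(beta, bank, mode="linearized", model=model)
            ideal = channel_gains(beta, bank, mode="ideal", model=model)
            np.testing.assert_allclose(lin.gains, ideal.gains, rtol=0.40)

    def test_bad_mode_rejected(self, bank, model):
        with pytest.raises(ValueError):
            channel_gains(1.0, bank, mode="magic", model=model)
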