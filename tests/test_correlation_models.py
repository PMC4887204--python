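"""Correlation-model evaluation and Levenberg-Marquardt fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphograd.correlation_models import (
    CorrelationCurve,
    InvalidParameterError,
    ObservationVolume,
    TripletDiffusionParams,
    acf_2d_1c_triplet,
    acf_3d_1c_triplet,
    acf_3d_2c_triplet,
    ccf_model,
    diffusion_from_tau,
    fit_correlation,
)
from morphograd.synthetic import GroundTruth, default_lag_grid, synth_correlation_curve


def direct_3d1c(n, f, tt, td, sr, ginf, tau):
    """Independent term-by-term evaluation of the 3D one-component model."""
    trip = 1 + (f / (1 - f)) * math.exp(-tau / tt) if f else 1.0
    return (1 / n) * trip * (1 + tau / td) ** -1 \
        * (1 + sr ** 2 * tau / td) ** -0.5 + ginf


class TestModelValues:
    def test_amplitude_at_short_lag_is_inverse_particle_number(self):
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1.0],
                                   structure_ratio=1.0)
        assert acf_3d_1c_triplet(p, 1e-12) == pytest.approx(1.0, rel=1e-9)

    def test_3d_value_at_tau_equal_tau_d(self):
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1.0],
                                   structure_ratio=1.0)
        assert acf_3d_1c_triplet(p, 1.0) == pytest.approx(0.5 / math.sqrt(2))

    def test_3d_with_triplet_matches_direct_substitution(self):
        p = TripletDiffusionParams(n_particles=2.0, tau_d=[1e-3], f_trip=0.2,
                                   tau_trip=1e-5, structure_ratio=0.2)
        expected = direct_3d1c(2.0, 0.2, 1e-5, 1e-3, 0.2, 0.0, 1e-4)
        assert acf_3d_1c_triplet(p, 1e-4) == pytest.approx(expected, rel=1e-12)

    def test_2d_value_at_tau_equal_tau_d(self):
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1.0])
        assert acf_2d_1c_triplet(p, 1.0) == pytest.approx(0.5)

    def test_2d_long_lag_limit_is_offset(self):
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-3], g_inf=0.01)
        assert acf_2d_1c_triplet(p, 1e8) == pytest.approx(0.01, abs=1e-9)

    def test_2d_with_triplet_matches_direct_substitution(self):
        n, f, tt, td, ginf, tau = 4.0, 0.1, 5e-6, 2e-3, 0.001, 2e-3
        trip = 1 + (f / (1 - f)) * math.exp(-tau / tt)
        expected = trip / n / (1 + tau / td) + ginf
        p = TripletDiffusionParams(n_particles=n, tau_d=[td], f_trip=f,
                                   tau_trip=tt, g_inf=ginf)
        assert acf_2d_1c_triplet(p, tau) == pytest.approx(expected, rel=1e-12)

    def test_ccf_is_simple_lorentzian(self):
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1.0])
        assert ccf_model(p, 3.0) == pytest.approx(0.25)
        assert ccf_model(p, 1e-12) == pytest.approx(1.0, rel=1e-9)

    def test_ccf_equals_2d_model_without_triplet(self):
        lag = default_lag_grid(50)
        p = TripletDiffusionParams(n_particles=3.0, tau_d=[2e-4], g_inf=0.002)
        np.testing.assert_allclose(ccf_model(p, lag),
                                   acf_2d_1c_triplet(p, lag), rtol=1e-12)


class TestTwoComponent:
    def test_degenerate_fraction_reduces_to_one_component(self):
        lag = default_lag_grid(50)
        p2 = TripletDiffusionParams(n_particles=2.0, tau_d=[1e-4, 1e-2],
                                    frac=[1.0, 0.0], structure_ratio=0.2)
        p1 = TripletDiffusionParams(n_particles=2.0, tau_d=[1e-4],
                                    structure_ratio=0.2)
        np.testing.assert_allclose(acf_3d_2c_triplet(p2, lag),
                                   acf_3d_1c_triplet(p1, lag), rtol=1e-12)

    def test_identical_components_collapse(self):
        lag = default_lag_grid(50)
        p2 = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-3, 1e-3],
                                    frac=[0.5, 0.5], structure_ratio=0.2)
        p1 = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-3],
                                    structure_ratio=0.2)
        np.testing.assert_allclose(acf_3d_2c_triplet(p2, lag),
                                   acf_3d_1c_triplet(p1, lag), rtol=1e-12)

    def test_mixture_matches_direct_substitution(self):
        tau = 1e-3
        expected = sum(
            f * (1 + tau / td) ** -1 * (1 + 0.04 * tau / td) ** -0.5
            for f, td in [(0.3, 1e-4), (0.7, 1e-2)])
        p = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-4, 1e-2],
                                   frac=[0.3, 0.7], structure_ratio=0.2)
        assert acf_3d_2c_triplet(p, tau) == pytest.approx(expected, rel=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            TripletDiffusionParams(n_particles=1.0, tau_d=[1e-4, 1e-2],
                                   frac=[0.3, 0.6])


class TestInvariantsAndValidation:
    @given(n=st.floats(0.5, 100), td=st.floats(1e-5, 1e-1),
           f=st.floats(0, 0.4), sr=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_models_decrease_monotonically_in_lag(self, n, td, f, sr):
        p = TripletDiffusionParams(n_particles=n, tau_d=[td], f_trip=f,
                                   tau_trip=1e-6, structure_ratio=sr)
        lag = np.logspace(-6, 1, 100)
        for model in (acf_3d_1c_triplet, acf_2d_1c_triplet):
            assert np.all(np.diff(model(p, lag)) < 0)

    @given(n=st.floats(0.5, 100), f=st.floats(0, 0.4))
    @settings(max_examples=50, deadline=None)
    def test_short_lag_limit_includes_triplet_boost(self, n, f):
        p = TripletDiffusionParams(n_particles=n, tau_d=[1e-3], f_trip=f,
                                   tau_trip=1e-5, structure_ratio=0.2)
        expected = 1.0 / (n * (1.0 - f))
        assert acf_3d_1c_triplet(p, 1e-12) == pytest.approx(expected, rel=1e-6)

    def test_curve_rejects_non_monotone_lags(self):
        with pytest.raises(ValueError):
            CorrelationCurve(lag=[1e-3, 1e-4], g=[1.0, 0.5])

    def test_curve_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            CorrelationCurve(lag=[1e-4, 1e-3], g=[1.0, 0.5], sigma=[0.1, 0.0])

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            TripletDiffusionParams(n_particles=-1.0, tau_d=[1e-3])
        with pytest.raises(InvalidParameterError):
            TripletDiffusionParams(n_particles=1.0, tau_d=[1e-3], f_trip=1.0)

    def test_effective_volume(self):
        vol = ObservationVolume(omega0=0.25, z0=1.25)
        assert vol.v_eff == pytest.approx(math.pi ** 1.5 * 0.25 ** 2 * 1.25,
                                          rel=1e-12)


class TestFitting:
    @pytest.mark.parametrize("model_kind,params", [
        ("3d1c", dict(n_particles=10.0, tau_d=[5e-4], f_trip=0.1,
                      tau_trip=1e-5)),
        ("2d1c", dict(n_particles=4.0, tau_d=[2e-3], f_trip=0.05,
                      tau_trip=5e-6)),
        ("3d2c", dict(n_particles=2.0, tau_d=[1e-4, 5e-3], frac=[0.4, 0.6])),
        ("ccf", dict(n_particles=8.0, tau_d=[1e-3])),
    ])
    def test_exact_data_recovers_parameters(self, model_kind, params, volume):
        from morphograd.correlation_models import _MODEL_FUNCS

        truth = TripletDiffusionParams(structure_ratio=0.2, **params)
        lag = default_lag_grid()
        curve = CorrelationCurve(lag=lag, g=_MODEL_FUNCS[model_kind](truth, lag))
        init = TripletDiffusionParams(
            n_particles=truth.n_particles * 2,
            tau_d=[t * 3 for t in truth.tau_d],
            frac=[0.5] * len(truth.tau_d) if len(truth.tau_d) == 2 else [1.0],
            f_trip=0.02 if model_kind != "ccf" else 0.0,
            structure_ratio=0.2)
        fit = fit_correlation(curve, model_kind, init, volume=volume)
        assert fit.converged
        assert fit.params.n_particles == pytest.approx(truth.n_particles,
                                                       rel=1e-5)
        for got, want in zip(fit.params.tau_d, truth.tau_d):
            assert got == pytest.approx(want, rel=1e-5)

    def test_noisy_curve_recovers_diffusion_within_ten_percent(self, volume):
        truth = GroundTruth(d_true=60.0, n_true=10.0, noise_level=0.02,
                            seed=7)
        curve, _ = synth_correlation_curve(truth, volume=volume)
        init = TripletDiffusionParams(n_particles=5.0, tau_d=[1e-3],
                                      structure_ratio=0.2)
        fit = fit_correlation(curve, "3d1c", init, volume=volume)
        assert fit.converged
        assert fit.diffusion_coeff[0] == pytest.approx(60.0, rel=0.10)

    def test_two_component_data_fits_worse_with_one_component(self, volume):
        truth = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-4, 1e-2],
                                       frac=[0.3, 0.7], structure_ratio=0.2)
        lag = default_lag_grid()
        curve = CorrelationCurve(lag=lag, g=acf_3d_2c_triplet(truth, lag))
        f1 = fit_correlation(curve, "3d1c", TripletDiffusionParams(
            n_particles=1.0, tau_d=[1e-3], structure_ratio=0.2), volume=volume)
        f2 = fit_correlation(curve, "3d2c", TripletDiffusionParams(
            n_particles=1.0, tau_d=[5e-5, 5e-3], frac=[0.5, 0.5],
            structure_ratio=0.2), volume=volume)
        assert f1.residual_norm > f2.residual_norm

    def test_constant_curve_reports_failure_not_exception(self):
        curve = CorrelationCurve(lag=default_lag_grid(30),
                                 g=np.full(30, 0.5))
        fit = fit_correlation(curve, "3d1c", TripletDiffusionParams(
            n_particles=1.0, tau_d=[1e-3]))
        assert not fit.converged

    def test_two_component_result_sorted_by_tau(self, volume):
        truth = TripletDiffusionParams(n_particles=1.0, tau_d=[1e-4, 1e-2],
                                       frac=[0.3, 0.7], structure_ratio=0.2)
        lag = default_lag_grid()
        curve = CorrelationCurve(lag=lag, g=acf_3d_2c_triplet(truth, lag))
        fit = fit_correlation(curve, "3d2c", TripletDiffusionParams(
            n_particles=1.0, tau_d=[2e-2, 2e-4], frac=[0.6, 0.4],
            structure_ratio=0.2), volume=volume)
        assert fit.converged
        assert fit.params.tau_d[0] < fit.params.tau_d[1]

    def test_median_diffusion_error_below_five_percent_at_low_noise(
            self, volume):
        errors = []
        init = TripletDiffusionParams(n_particles=5.0, tau_d=[1e-3],
                                      structure_ratio=0.2)
        for seed in range(100):
            truth = GroundTruth(d_true=60.0, n_true=10.0, noise_level=0.01,
                                seed=seed)
            curve, _ = synth_correlation_curve(truth, volume=volume)
            fit = fit_correlation(curve, "3d1c", init, volume=volume)
            assert fit.converged
            errors.append(abs(fit.diffusion_coeff[0] - 60.0) / 60.0)
        assert np.median(errors) < 0.05


class TestDiffusionFromTau:
    def test_arithmetic(self):
        vol = ObservationVolume(omega0=0.2, z0=1.0)
        assert diffusion_from_tau(1e-3, vol) == pytest.approx(10.0)

    def test_typical_extracellular_value(self):
        vol = ObservationVolume(omega0=0.25, z0=1.25)
        assert diffusion_from_tau(2.604e-4, vol) == pytest.approx(60.0,
                                                                  rel=1e-2)

    def test_quadratic_scaling_in_beam_waist(self):
        v1 = ObservationVolume(omega0=0.2, z0=1.0)
        v2 = ObservationVolume(omega0=0.4, z0=1.0)
        assert diffusion_from_tau(1e-3, v2) == pytest.approx(
            4 * diffusion_from_tau(1e-3, v1))
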