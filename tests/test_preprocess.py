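"""Pre-processing identities and properties: polynomial annihilation,
rubberband hull geometry, wavelet shrinkage, normalisation, the channel bank
and train-fold standardisation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ramancnn.baselines import BASELINE_METHODS, RegistryError, whittaker_smooth
from ramancnn.dataset import DegenerateInputError, Spectrum
from ramancnn.preprocess import (
    SD_FLOOR,
    channel_bank,
    fit_standardizer,
    manual_pipeline,
    polynomial_baseline_subtract,
    rubberband_subtract,
    standardize,
    vector_normalize,
    wavelet_denoise,
)

RNG = np.random.default_rng(0)


class TestPolynomialBaseline:
    def test_annihilates_degree5_polynomial(self):
        x = np.linspace(-1, 1, 300)
        coef = np.array([3.0, -2.0, 1.5, 0.7, -0.3, 0.2])
        y = np.polynomial.polynomial.polyval(x, coef)
        out = polynomial_baseline_subtract(y, 5)
        assert np.max(np.abs(out)) < 1e-8 * np.max(np.abs(y))

    @pytest.mark.parametrize("order", [0, 1, 2, 3, 4, 5])
    def test_annihilates_all_lower_degrees(self, order):
        x = np.linspace(-1, 1, 200)
        rng = np.random.default_rng(order)
        coef = rng.normal(0, 1, order + 1)
        y = np.polynomial.polynomial.polyval(x, coef)
        out = polynomial_baseline_subtract(y, 5)
        assert np.max(np.abs(out)) < 1e-8 * max(np.max(np.abs(y)), 1.0)

    def test_constant_input_order_zero(self):
        out = polynomial_baseline_subtract(np.full(50, 7.3), 0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_peak_on_quadratic_recovered(self):
        grid = np.linspace(614, 1722, 500)
        x = np.linspace(-1, 1, 500)
        peak = 1.0 * np.exp(-0.5 * ((grid - 1200) / 20.0) ** 2)
        baseline = 2.0 + 0.8 * x + 0.5 * x**2
        out = polynomial_baseline_subtract(peak + baseline, 5)
        apex = int(np.argmax(peak))
        assert abs(out[apex] - 1.0) < 0.02  # apex within 2% of true amplitude

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            polynomial_baseline_subtract(np.ones(10), -1)


class TestRubberband:
    def test_linear_spectrum_maps_to_zero(self):
        x = np.linspace(0, 10, 50)
        out = rubberband_subtract(x, 3.0 * x + 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_convex_spectrum_maps_to_zero(self):
        x = np.linspace(-5, 5, 81)
        out = rubberband_subtract(x, x**2)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_peak_on_line_recovered(self):
        x = np.linspace(0, 100, 401)
        line = 0.5 * x + 2.0
        peak = 4.0 * np.exp(-0.5 * ((x - 50) / 5.0) ** 2)
        out = rubberband_subtract(x, peak + line)
        assert out[0] == 0.0 and out[-1] == 0.0
        apex = int(np.argmax(peak))
        assert abs(out[apex] - peak[apex]) < 0.05  # interpolation error only

    @settings(max_examples=100, deadline=None)
    @given(arrays(np.float64, st.integers(2, 60),
                  elements=st.floats(-1e3, 1e3, allow_nan=False)))
    def test_nonnegative_with_zero_endpoints(self, y):
        x = np.arange(y.size, dtype=float)
        out = rubberband_subtract(x, y)
        assert np.all(out >= 0.0)
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            rubberband_subtract(np.array([1.0, 0.5, 2.0]), np.ones(3))


class TestWaveletDenoise:
    def test_constant_signal_unchanged(self):
        y = np.full(128, 3.0)
        np.testing.assert_allclose(wavelet_denoise(y, 3), y, atol=1e-10)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 1024)
        out = wavelet_denoise(y, 3)
        assert out.var() < y.var()

    def test_smooth_peak_nearly_preserved(self):
        x = np.linspace(0, 1, 512)
        y = np.exp(-0.5 * ((x - 0.5) / 0.05) ** 2)
        out = wavelet_denoise(y, 3)
        assert np.max(np.abs(out - y)) < 0.05 * y.max()

    def test_length_preserved_odd_input(self):
        y = RNG.normal(0, 1, 1015)
        assert wavelet_denoise(y, 3).size == 1015

    def test_level_too_large_rejected(self):
        with pytest.raises(ValueError):
            wavelet_denoise(np.ones(16), 10)


class TestVectorNormalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(vector_normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_idempotent_and_scale_invariant(self):
        y = RNG.normal(0, 1, 64)
        once = vector_normalize(y)
        np.testing.assert_allclose(vector_normalize(once), once, atol=1e-12)
        np.testing.assert_allclose(vector_normalize(17.0 * y), once, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(2, 100),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_unit_norm(self, y):
        if np.linalg.norm(y) == 0:
            return
        assert abs(np.linalg.norm(vector_normalize(y)) - 1.0) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            vector_normalize(np.zeros(5))


class TestManualPipeline:
    def test_baseline_free_peak_survives(self):
        grid = np.linspace(614.0, 1722.0, 507)
        peak = np.exp(-0.5 * ((grid - 1200.0) / 30.0) ** 2)
        s = Spectrum(grid, peak + 0.5, "P", "OA", "deep", "A")
        out = manual_pipeline(s)
        # after the pipeline the shape matches the bare peak up to norm
        got = out.intensities / np.max(out.intensities)
        assert np.max(np.abs(got - peak)) < 0.05

    def test_metadata_preserved_and_deterministic(self, toy_spectrum):
        a = manual_pipeline(toy_spectrum)
        b = manual_pipeline(toy_spectrum)
        assert a.metadata == toy_spectrum.metadata
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_zero_spectrum_degenerate(self, tiny_grid):
        s = Spectrum(tiny_grid, np.zeros(tiny_grid.size), "P", "OA", "deep", "A")
        with pytest.raises(DegenerateInputError):
            manual_pipeline(s)


class TestChannelBank:
    def test_empty_method_list_gives_raw_only(self, toy_spectrum):
        mc = channel_bank(toy_spectrum, [])
        assert mc.channels.shape == (1, toy_spectrum.intensities.size)
        assert mc.channel_names == ("raw",)

    def test_default_bank_is_eight_channels(self, toy_spectrum):
        mc = channel_bank(toy_spectrum)
        assert mc.channels.shape[0] == 8
        assert mc.channel_names[0] == "raw"
        assert set(mc.channel_names[1:]) == set(BASELINE_METHODS)

    def test_channel_zero_is_bitwise_raw(self, toy_spectrum):
        mc = channel_bank(toy_spectrum)
        np.testing.assert_array_equal(mc.channels[0], toy_spectrum.intensities)

    def test_full_grid_shape(self):
        grid = np.linspace(614.0, 1722.0, 1015)
        rng = np.random.default_rng(0)
        y = np.exp(-0.5 * ((grid - 1330) / 10.0) ** 2) + rng.normal(0, 0.01, 1015)
        s = Spectrum(grid, y, "P", "OA", "deep", "A")
        mc = channel_bank(s)
        assert mc.channels.shape == (8, 1015)

    def test_zero_baseline_peak_corrections_small_at_apex(self):
        # narrow peak on the full-resolution grid, as acquired in practice
        grid = np.linspace(614.0, 1722.0, 1015)
        peak = np.exp(-0.5 * ((grid - 1330.0) / 10.0) ** 2)
        s = Spectrum(grid, peak, "P", "OA", "deep", "A")
        mc = channel_bank(s)
        apex = int(np.argmax(peak))
        for row, name in zip(mc.channels[1:], mc.channel_names[1:]):
            assert abs(row[apex] - peak[apex]) < 0.1 * peak[apex], name

    def test_unregistered_method_rejected(self, toy_spectrum):
        with pytest.raises(RegistryError, match="not_a_method"):
            channel_bank(toy_spectrum, ["not_a_method"])

    def test_all_channels_finite(self, small_cohort):
        for s in list(small_cohort)[:3]:
            assert np.all(np.isfinite(channel_bank(s).channels))


class TestWhittaker:
    def test_matches_dense_solution(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 40)
        w = rng.random(40) + 0.1
        lam = 50.0
        d2 = np.diff(np.eye(40), 2, axis=0)
        dense = np.linalg.solve(np.diag(w) + lam * d2.T @ d2, w * y)
        np.testing.assert_allclose(whittaker_smooth(y, lam, w), dense, atol=1e-10)


class TestStandardization:
    def test_population_convention(self):
        stack = np.zeros((2, 1, 3))
        stack[1] = 2.0
        stats = fit_standardizer(stack)
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(stats.sd, 1.0)

    def test_identical_spectra_floor_sd(self):
        stack = np.ones((5, 2, 4))
        stats = fit_standardizer(stack)
        np.testing.assert_allclose(stats.sd, SD_FLOOR)

    def test_closure_on_training_set(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(3, 2, (50, 2, 30))
        stats = fit_standardizer(stack)
        z = standardize(stack, stats)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-6)

    def test_round_trip_inversion(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(0, 1, (10, 1, 20))
        stats = fit_standardizer(stack)
        z = standardize(stack, stats)
        back = z * stats.sd + stats.mean
        np.testing.assert_allclose(back, stack, atol=1e-9)

    def test_mean_maps_to_zero_and_mean_plus_sd_to_one(self):
        rng = np.random.default_rng(4)
        stack = rng.normal(0, 1, (20, 1, 5))
        stats = fit_standardizer(stack)
        np.testing.assert_allclose(standardize(stats.mean[None], stats), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            standardize((stats.mean + stats.sd)[None], stats), 1.0, atol=1e-12
        )

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((1, 1, 5)))

    def test_shape_mismatch_rejected(self):
        stats = fit_standardizer(np.ones((3, 2, 5)) * np.arange(3)[:, None, None])
        with pytest.raises(ValueError):
            standardize(np.ones((4, 2, 6)), stats)
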