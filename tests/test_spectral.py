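"""Core spectral primitives: forward model, FT, phasing, baseline, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from hp13c.spectral import (
    FIDRecord,
    PpmWindow,
    Resonance,
    SpectralAxis,
    SpectralWindowError,
    apply_phase,
    estimate_noise_rms,
    fid_to_spectrum,
    integrate_window,
    model_fid,
    quadratic_baseline_correct,
    zero_order_phase,
)

AXIS = SpectralAxis(1024, 6000.0, 75.4, 145.0)


class TestModelFID:
    def test_empty_resonance_list_gives_zero_fid(self):
        fid = model_fid([], AXIS)
        assert np.all(fid.samples == 0)

    def test_t0_sample_modulus_equals_amplitude(self):
        fid = model_fid([Resonance(150.0, 2.5, 40.0, 0.9)], AXIS)
        assert abs(fid.samples[0]) == pytest.approx(2.5)

    def test_out_of_window_resonance_rejected(self):
        with pytest.raises(SpectralWindowError, match="outside the spectral"):
            model_fid([Resonance(400.0, 1.0, 10.0)], AXIS)

    def test_peak_height_matches_continuous_ft_oracle(self):
        """Absorption peak height approximates A/(pi*fwhm) per the continuous FT.

        Oracle: numerically integrate the continuous one-sided Fourier
        transform of A*exp(-pi*fwhm*t) at the resonance frequency.
        """
        amp, fwhm = 1.0, 50.0
        axis = SpectralAxis(1024, 6000.0, 75.4, 173.0)
        fid = model_fid([Resonance(173.0, amp, fwhm)], axis)
        spec = fid_to_spectrum(fid)
        height = spec.values.real.max()
        oracle, _ = quad(lambda t: amp * np.exp(-np.pi * fwhm * t), 0, np.inf)
        assert oracle == pytest.approx(amp / (np.pi * fwhm), rel=1e-8)
        assert height == pytest.approx(oracle, rel=0.03)


class TestFourierTransform:
    def test_zero_fid_gives_zero_spectrum(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        assert np.all(spec.values == 0)

    def test_pure_tone_lands_in_single_bin(self):
        # offset chosen on the frequency grid: bin spacing is bw/n
        k = 37
        f = k * AXIS.bandwidth_hz / AXIS.n_points
        t = AXIS.times_s
        fid = FIDRecord(np.exp(2j * np.pi * f * t), AXIS)
        spec = fid_to_spectrum(fid)
        mags = np.abs(spec.values)
        peak_idx = int(np.argmax(mags))
        expected_ppm = AXIS.carrier_ppm + f / AXIS.spectrometer_freq_mhz
        assert spec.axis.ppm[peak_idx] == pytest.approx(expected_ppm, abs=1e-9)
        others = np.delete(mags, peak_idx)
        assert others.max() < 1e-10 * mags[peak_idx]

    def test_lorentzian_peak_location_vs_zero_filled_oracle(self):
        """Peak ppm within half a bin of the true shift (8x zero-fill oracle)."""
        shift = 151.3
        fid = model_fid([Resonance(shift, 1.0, 20.0)], AXIS)
        spec = fid_to_spectrum(fid)
        coarse_ppm = spec.axis.ppm[int(np.argmax(spec.values.real))]
        # oracle: 8x zero-filled transform localises the true maximum
        padded = np.concatenate([fid.samples, np.zeros(7 * AXIS.n_points)])
        fine = np.fft.fftshift(np.fft.fft(padded))
        fine_freq = np.fft.fftshift(np.fft.fftfreq(len(padded), d=AXIS.dwell_s))
        fine_ppm = AXIS.carrier_ppm + fine_freq / AXIS.spectrometer_freq_mhz
        oracle_ppm = fine_ppm[int(np.argmax(fine.real))]
        assert abs(oracle_ppm - shift) <= AXIS.ppm_bin_width
        assert abs(coarse_ppm - oracle_ppm) <= AXIS.ppm_bin_width / 2 + 1e-12

    def test_parseval_exact(self):
        rng = np.random.default_rng(7)
        samples = rng.normal(size=AXIS.n_points) + 1j * rng.normal(size=AXIS.n_points)
        fid = FIDRecord(samples, AXIS)
        spec = fid_to_spectrum(fid)
        e_time = np.sum(np.abs(fid.samples) ** 2) * AXIS.dwell_s
        bin_hz = AXIS.bandwidth_hz / AXIS.n_points
        e_freq = np.sum(np.abs(spec.values) ** 2) * bin_hz
        assert e_freq == pytest.approx(e_time, rel=1e-12)


class TestZeroOrderPhase:
    WINDOW = [PpmWindow(155.0, 164.0)]

    def test_already_phased_is_fixed_point(self, lorentzian_spectrum):
        spec = lorentzian_spectrum()
        out = zero_order_phase(spec, self.WINDOW)
        phi = out.phase_applied_rad
        assert min(phi, 2 * np.pi - phi) < 0.02

    def test_recovers_applied_phase(self, lorentzian_spectrum):
        spec = apply_phase(lorentzian_spectrum(), 0.7)
        out = zero_order_phase(spec, self.WINDOW)
        assert out.phase_applied_rad == pytest.approx(0.7, abs=0.02)

    def test_two_peak_common_phase_vs_grid_oracle(self, bicarb_axis):
        fid = model_fid(
            [Resonance(159.5, 1.0, 8.0, 1.2), Resonance(125.0, 0.4, 8.0, 1.2)],
            bicarb_axis,
        )
        windows = [PpmWindow(123, 127), PpmWindow(156, 163)]
        out = zero_order_phase(fid_to_spectrum(fid), windows)
        assert out.phase_applied_rad == pytest.approx(1.2, abs=0.02)
        # both peaks absorption mode: imaginary residual small over the windows
        ppm = out.axis.ppm
        imag_total = sum(
            abs(np.trapezoid(out.values.imag[w.contains(ppm)], ppm[w.contains(ppm)]))
            for w in windows
        )
        real_total = sum(
            np.trapezoid(out.values.real[w.contains(ppm)], ppm[w.contains(ppm)])
            for w in windows
        )
        # dispersion tails of each line leak into the other line's window,
        # so the combined imaginary residual is ~1%, not exactly zero
        assert imag_total < 0.02 * real_total
        # grid-search oracle over phi agrees with the optimiser
        grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        spec = fid_to_spectrum(fid)
        scores = []
        for phi in grid:
            rot = spec.values * np.exp(-1j * phi)
            scores.append(
                sum(
                    np.trapezoid(rot.real[w.contains(ppm)], ppm[w.contains(ppm)])
                    for w in windows
                )
            )
        oracle_phi = grid[int(np.argmax(scores))]
        assert out.phase_applied_rad == pytest.approx(oracle_phi, abs=2 * np.pi / 360)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(phi=st.floats(0.0, 2 * np.pi - 1e-6))
    def test_phase_composition_property(self, phi):
        fid = model_fid([Resonance(159.5, 1.0, 8.0)], AXIS)
        spec = fid_to_spectrum(fid)
        rotated = apply_phase(spec, phi)
        out = zero_order_phase(rotated, self.WINDOW)
        # the recovered orientation is identical for every applied phase
        ref = zero_order_phase(spec, self.WINDOW)
        np.testing.assert_allclose(out.values.real, ref.values.real, atol=1e-9)

    def test_window_outside_axis_rejected(self):
        fid = model_fid([Resonance(159.5, 1.0, 8.0)], AXIS)
        with pytest.raises(SpectralWindowError):
            zero_order_phase(fid_to_spectrum(fid), [PpmWindow(400, 410)])


class TestBaseline:
    EXCLUDES = [PpmWindow(122, 128), PpmWindow(155, 164)]

    def test_known_quadratic_removed(self, lorentzian_spectrum):
        """Adding a known quadratic changes nothing after correction."""
        clean = quadratic_baseline_correct(lorentzian_spectrum(), self.EXCLUDES)
        dirty = lorentzian_spectrum()
        ppm = dirty.axis.ppm
        dirty.values = dirty.values + (2.0 + 0.5 * ppm + 0.01 * ppm**2)
        out = quadratic_baseline_correct(dirty, self.EXCLUDES)
        mask = np.ones(len(ppm), bool)
        for w in self.EXCLUDES:
            mask &= ~w.contains(ppm)
        resid = out.values.real[mask] - clean.values.real[mask]
        assert np.sqrt(np.mean(resid**2)) < 1e-10

    def test_flat_zero_baseline_noop(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        out = quadratic_baseline_correct(spec, self.EXCLUDES)
        np.testing.assert_array_equal(out.values, spec.values)

    def test_window_integral_recovers_analytic_lorentzian(self, lorentzian_spectrum):
        """Baseline-corrected window integral matches the closed form within 1%.

        Oracle: an absorption Lorentzian of amplitude A and FWHM d has total
        integral A/2 (in Hz); a window of half-width h about the peak captures
        the fraction (2/pi)*arctan(2h/d).
        """
        # linewidth chosen so the FID fully decays within the acquisition
        # window (truncation ringing would otherwise cost ~1% of the integral)
        fwhm = 40.0
        window = PpmWindow(156, 163)
        f0 = AXIS.spectrometer_freq_mhz
        half_hz = 0.5 * window.width * f0
        analytic = (0.5 / f0) * (2 / np.pi) * np.arctan(2 * half_hz / fwhm)
        dirty = lorentzian_spectrum(shift_ppm=159.5, amplitude=1.0, linewidth_hz=fwhm)
        ppm = dirty.axis.ppm
        dirty.values = dirty.values + (0.3 - 0.004 * ppm + 1e-5 * ppm**2)
        # anchor the baseline well clear of the Lorentzian tails
        out = quadratic_baseline_correct(
            dirty, [PpmWindow(117, 133), PpmWindow(150, 169)]
        )
        assert integrate_window(out, window) == pytest.approx(analytic, rel=0.01)

    def test_too_few_baseline_points_rejected(self, lorentzian_spectrum):
        spec = lorentzian_spectrum()
        lo, hi = spec.axis.ppm_range
        with pytest.raises(SpectralWindowError, match="baseline points"):
            quadratic_baseline_correct(spec, [PpmWindow(lo - 1, hi + 1)])


class TestIntegrateWindow:
    def test_zero_spectrum(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        assert integrate_window(spec, PpmWindow(130, 140)) == 0.0

    def test_unit_rectangle_gives_window_width(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        spec.values = np.ones(AXIS.n_points, dtype=complex)
        w = PpmWindow(131.7, 140.4)
        assert integrate_window(spec, w) == pytest.approx(w.width, rel=1e-12)

    def test_captures_96pct_of_analytic_lorentzian_integral(self, lorentzian_spectrum):
        fwhm = 8.0
        spec = lorentzian_spectrum(shift_ppm=145.0, amplitude=1.0, linewidth_hz=fwhm)
        half_ppm = 10 * fwhm / spec.axis.spectrometer_freq_mhz
        w = PpmWindow(145.0 - half_ppm, 145.0 + half_ppm)
        total = 0.5 / spec.axis.spectrometer_freq_mhz  # A/2 in Hz -> ppm units
        assert integrate_window(spec, w) >= 0.96 * total

    def test_no_overlap_rejected(self, lorentzian_spectrum):
        with pytest.raises(SpectralWindowError):
            integrate_window(lorentzian_spectrum(), PpmWindow(300, 310))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        split=st.floats(133.0, 137.0),
    )
    def test_linear_and_additive(self, scale, split):
        spec = fid_to_spectrum(model_fid([Resonance(135.0, 1.0, 20.0)], AXIS))
        w = PpmWindow(130.0, 140.0)
        whole = integrate_window(spec, w)
        left = integrate_window(spec, PpmWindow(130.0, split))
        right = integrate_window(spec, PpmWindow(split, 140.0))
        assert left + right == pytest.approx(whole, rel=1e-9)
        scaled = spec
        scaled.values = scaled.values * scale
        assert integrate_window(scaled, w) == pytest.approx(scale * whole, rel=1e-9)


class TestNoiseEstimate:
    WINDOW = PpmWindow(108.0, 120.0)

    def test_zero_spectrum_gives_zero(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        assert estimate_noise_rms(spec, self.WINDOW) == 0.0

    def test_constant_offset_gives_zero(self):
        spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
        spec.values = spec.values + 3.3
        assert estimate_noise_rms(spec, self.WINDOW) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_noise_recovered_within_20pct(self):
        """Monte-Carlo over seeds: frequency-domain noise sigma recovered."""
        sigma = 0.37
        n_pts = int(self.WINDOW.contains(AXIS.ppm).sum())
        assert n_pts >= 128
        estimates = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            spec = fid_to_spectrum(FIDRecord(np.zeros(AXIS.n_points), AXIS))
            spec.values = rng.normal(0, sigma, AXIS.n_points) + 0j
            estimates.append(estimate_noise_rms(spec, self.WINDOW))
        estimates = np.asarray(estimates)
        assert np.all(np.abs(estimates - sigma) < 0.2 * sigma)

    def test_overlap_with_signal_window_rejected(self, lorentzian_spectrum):
        with pytest.raises(SpectralWindowError, match="overlaps"):
            estimate_noise_rms(
                lorentzian_spectrum(), self.WINDOW, signal_windows=[PpmWindow(115, 125)]
            )
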