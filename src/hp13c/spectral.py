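"""Core spectral data model and processing for hyperpolarized 13C MRS.

This module defines the shared vocabulary of the package — spectral axes,
Lorentzian resonances, free induction decays (FIDs) and spectra — together
with the processing primitives every downstream analysis composes:

* a forward FID model (sum of exponentially decaying complex sinusoids),
* the Fourier transform between time and frequency domains,
* zero-order phase correction,
* quadratic baseline correction,
* trapezoidal window integration, and
* RMS noise estimation from a signal-free region.

Conventions
-----------
The discrete Fourier transform is scaled by the dwell time (sum × dwell), so
the spectrum approximates the continuous Fourier transform of the decaying
signal. Under this convention an absorption-mode Lorentzian of time-domain
amplitude ``A`` and full width at half maximum ``fwhm`` (Hz) has peak height
``A / (pi * fwhm)``, which is what makes the SNR gate used for MRSI quality
control well defined.

The ppm axis ascends with frequency: ``ppm(f) = carrier_ppm +
f_hz / spectrometer_freq_mhz``, the usual 13C convention in which lactate
(185 ppm) sits to the left of pyruvate (173 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import minimize_scalar

__all__ = [
    "SpectralAxis",
    "Resonance",
    "FIDRecord",
    "Spectrum",
    "PpmWindow",
    "model_fid",
    "fid_to_spectrum",
    "zero_order_phase",
    "quadratic_baseline_correct",
    "integrate_window",
    "estimate_noise_rms",
]


class SpectralWindowError(ValueError):
    """A ppm window falls outside (or degenerately inside) the spectral axis."""


@dataclass(frozen=True)
class SpectralAxis:
    """Sampling grid shared by a FID and its spectrum.

    Parameters
    ----------
    n_points : int
        Number of complex samples (>= 2).
    bandwidth_hz : float
        Spectral width / sampling rate in Hz; dwell time is ``1/bandwidth_hz``.
    spectrometer_freq_mhz : float
        13C Larmor frequency in MHz (75.4 MHz at 7 T).
    carrier_ppm : float
        Chemical shift at the centre of the spectral window.
    """

    n_points: int
    bandwidth_hz: float
    spectrometer_freq_mhz: float
    carrier_ppm: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.bandwidth_hz <= 0:
            raise ValueError(f"bandwidth_hz must be > 0, got {self.bandwidth_hz}")
        if self.spectrometer_freq_mhz <= 0:
            raise ValueError("spectrometer_freq_mhz must be > 0")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times t_k = k * dwell."""
        return np.arange(self.n_points) * self.dwell_s

    @property
    def freq_hz(self) -> np.ndarray:
        """Frequency offsets from the carrier, ascending (fftshift order)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_s))

    @property
    def ppm(self) -> np.ndarray:
        """Chemical-shift axis, strictly ascending."""
        return self.carrier_ppm + self.freq_hz / self.spectrometer_freq_mhz

    @property
    def ppm_bin_width(self) -> float:
        return (self.bandwidth_hz / self.n_points) / self.spectrometer_freq_mhz

    @property
    def ppm_range(self) -> tuple[float, float]:
        p = self.ppm
        return float(p[0]), float(p[-1])

    def ppm_to_hz(self, shift_ppm: float) -> float:
        """Offset in Hz of a chemical shift from the carrier."""
        return (shift_ppm - self.carrier_ppm) * self.spectrometer_freq_mhz

    def contains_ppm(self, shift_ppm: float) -> bool:
        lo, hi = self.ppm_range
        return lo <= shift_ppm <= hi


@dataclass(frozen=True)
class Resonance:
    """One Lorentzian spectral line.

    ``amplitude`` is the time-domain magnitude at t=0 (arbitrary units);
    ``linewidth_hz`` is the absorption-mode full width at half maximum.
    """

    shift_ppm: float
    amplitude: float
    linewidth_hz: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.linewidth_hz <= 0:
            raise ValueError(f"linewidth_hz must be > 0, got {self.linewidth_hz}")


@dataclass
class FIDRecord:
    """Complex time-domain signal plus acquisition metadata."""

    samples: np.ndarray
    axis: SpectralAxis
    timestamp_s: float | None = None
    flip_angle_deg: float | None = None
    tr_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or len(self.samples) != self.axis.n_points:
            raise ValueError(
                f"samples length {self.samples.shape} does not match axis "
                f"n_points={self.axis.n_points}"
            )
        if self.timestamp_s is not None and self.timestamp_s < 0:
            raise ValueError("timestamp_s must be >= 0")


@dataclass
class Spectrum:
    """Complex frequency-domain data on a :class:`SpectralAxis`.

    ``phase_applied_rad`` records any zero-order phase already applied;
    ``baseline_coeffs`` records a subtracted quadratic baseline (polynomial
    coefficients in ascending ppm powers) when baseline correction has run.
    """

    values: np.ndarray
    axis: SpectralAxis
    phase_applied_rad: float = 0.0
    baseline_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 1 or len(self.values) != self.axis.n_points:
            raise ValueError("values length does not match axis n_points")

    @property
    def real(self) -> np.ndarray:
        return self.values.real


@dataclass(frozen=True)
class PpmWindow:
    """Closed chemical-shift interval [ppm_lo, ppm_hi]."""

    ppm_lo: float
    ppm_hi: float

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(
                f"ppm_lo must be < ppm_hi, got [{self.ppm_lo}, {self.ppm_hi}]"
            )

    @property
    def width(self) -> float:
        return self.ppm_hi - self.ppm_lo

    @property
    def centre(self) -> float:
        return 0.5 * (self.ppm_lo + self.ppm_hi)

    def dilate(self, margin_ppm: float) -> "PpmWindow":
        return PpmWindow(self.ppm_lo - margin_ppm, self.ppm_hi + margin_ppm)

    def contains(self, ppm: float | np.ndarray):
        return (ppm >= self.ppm_lo) & (ppm <= self.ppm_hi)

    def overlaps_axis(self, axis: SpectralAxis) -> bool:
        lo, hi = axis.ppm_range
        return self.ppm_hi >= lo and self.ppm_lo <= hi


def model_fid(resonances: Sequence[Resonance], axis: SpectralAxis) -> FIDRecord:
    """Forward model: sum of decaying complex sinusoids.

    Sample k at time t_k is

        sum_j A_j exp(i phi_j) exp(i 2 pi f_j t_k - pi fwhm_j t_k)

    with f_j the offset of the resonance from the carrier in Hz. The decay
    constant ``pi * fwhm`` makes ``fwhm_j`` the absorption-mode FWHM in Hz.
    """
    for res in resonances:
        if not axis.contains_ppm(res.shift_ppm):
            lo, hi = axis.ppm_range
            raise SpectralWindowError(
                f"resonance at {res.shift_ppm} ppm lies outside the spectral "
                f"window [{lo:.2f}, {hi:.2f}] ppm"
            )
    t = axis.times_s
    samples = np.zeros(axis.n_points, dtype=np.complex128)
    for res in resonances:
        f = axis.ppm_to_hz(res.shift_ppm)
        samples += (
            res.amplitude
            * np.exp(1j * res.phase_rad)
            * np.exp((2j * np.pi * f - np.pi * res.linewidth_hz) * t)
        )
    return FIDRecord(samples=samples, axis=axis)


def fid_to_spectrum(fid: FIDRecord) -> Spectrum:
    """Discrete Fourier transform scaled by dwell time (continuous-FT style).

    The frequency axis is fftshifted so that the centre bin sits at the
    carrier; Parseval holds exactly:
    ``sum |fid|^2 * dwell == sum |spec|^2 * bin_width_hz``.
    """
    values = np.fft.fftshift(np.fft.fft(fid.samples)) * fid.axis.dwell_s
    return Spectrum(values=values, axis=fid.axis)


def _check_windows(axis: SpectralAxis, windows: Sequence[PpmWindow]) -> None:
    if not windows:
        raise SpectralWindowError("at least one ppm window is required")
    for w in windows:
        if not w.overlaps_axis(axis):
            lo, hi = axis.ppm_range
            raise SpectralWindowError(
                f"window [{w.ppm_lo}, {w.ppm_hi}] ppm does not overlap the "
                f"axis range [{lo:.2f}, {hi:.2f}] ppm"
            )


def zero_order_phase(
    spec: Spectrum, signal_windows: Sequence[PpmWindow]
) -> Spectrum:
    """Zero-order phase a spectrum to maximise its real integral over windows.

    The applied phase (the phi maximising ``integral Re[exp(-i phi) S]`` over
    ``signal_windows``) is found from a 360-point grid followed by bounded
    1-D refinement, and recorded in ``phase_applied_rad``.
    """
    _check_windows(spec.axis, signal_windows)
    ppm = spec.axis.ppm
    # Real integral of exp(-i phi) S is Re[exp(-i phi) * C] with C the sum of
    # the complex integrals over the (disjoint) windows; grid + refine.
    c = 0.0 + 0.0j
    n_inside = 0
    for w in signal_windows:
        mask = w.contains(ppm)
        n_inside += int(mask.sum())
        if mask.sum() > 1:
            c += np.trapezoid(spec.values[mask], ppm[mask])
        elif mask.sum() == 1:
            c += spec.values[mask][0]
    if n_inside == 0:
        raise SpectralWindowError("no axis points fall inside the signal windows")

    def neg_real_integral(phi: float) -> float:
        return -float(np.real(np.exp(-1j * phi) * c))

    grid = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
    best = grid[np.argmin([neg_real_integral(p) for p in grid])]
    res = minimize_scalar(
        neg_real_integral,
        bounds=(best - 2 * np.pi / 360, best + 2 * np.pi / 360),
        method="bounded",
        options={"xatol": 1e-10},
    )
    phi = float(res.x) % (2 * np.pi)
    return Spectrum(
        values=spec.values * np.exp(-1j * phi),
        axis=spec.axis,
        phase_applied_rad=phi,
        baseline_coeffs=spec.baseline_coeffs,
    )


def quadratic_baseline_correct(
    spec: Spectrum, exclude_windows: Sequence[PpmWindow]
) -> Spectrum:
    """Fit and subtract a quadratic-in-ppm baseline from the real part.

    The quadratic is least-squares fitted to real-part points lying outside
    every window in ``exclude_windows`` (the peak regions); the imaginary part
    is untouched. At least three baseline points must remain.
    """
    ppm = spec.axis.ppm
    mask = np.ones(len(ppm), dtype=bool)
    for w in exclude_windows:
        mask &= ~w.contains(ppm)
    if mask.sum() < 3:
        raise SpectralWindowError(
            f"only {int(mask.sum())} baseline points remain outside the "
            "excluded windows; need at least 3 for a quadratic fit"
        )
    poly = Polynomial.fit(ppm[mask], spec.values.real[mask], deg=2)
    baseline = poly(ppm)
    coeffs = poly.convert().coef  # ascending powers of raw ppm
    values = (spec.values.real - baseline) + 1j * spec.values.imag
    return Spectrum(
        values=values,
        axis=spec.axis,
        phase_applied_rad=spec.phase_applied_rad,
        baseline_coeffs=np.asarray(coeffs, dtype=float),
    )


def integrate_window(spec: Spectrum, window: PpmWindow) -> float:
    """Trapezoidal integral of the real part over a ppm window (signal·ppm).

    Window bounds falling between axis points are included by linear
    interpolation, so the result varies continuously with the bounds and is
    additive over adjacent windows. Linear in the spectrum.
    """
    if not window.overlaps_axis(spec.axis):
        raise SpectralWindowError(
            f"window [{window.ppm_lo}, {window.ppm_hi}] ppm does not overlap the axis"
        )
    ppm = spec.axis.ppm
    lo_ax, hi_ax = spec.axis.ppm_range
    lo = max(window.ppm_lo, lo_ax)
    hi = min(window.ppm_hi, hi_ax)
    interior = (ppm > lo) & (ppm < hi)
    xs = np.concatenate(([lo], ppm[interior], [hi]))
    re = spec.values.real
    ys = np.concatenate(
        ([np.interp(lo, ppm, re)], re[interior], [np.interp(hi, ppm, re)])
    )
    return float(np.trapezoid(ys, xs))


def estimate_noise_rms(
    spec: Spectrum,
    noise_window: PpmWindow,
    signal_windows: Sequence[PpmWindow] = (),
    min_points: int = 32,
) -> float:
    """RMS of the mean-subtracted real part over a signal-free window.

    Raises if the noise window overlaps any declared signal window or holds
    fewer than ``min_points`` axis points.
    """
    for w in signal_windows:
        if noise_window.ppm_hi >= w.ppm_lo and noise_window.ppm_lo <= w.ppm_hi:
            raise SpectralWindowError(
                f"noise window [{noise_window.ppm_lo}, {noise_window.ppm_hi}] ppm "
                f"overlaps declared signal window [{w.ppm_lo}, {w.ppm_hi}] ppm"
            )
    ppm = spec.axis.ppm
    mask = noise_window.contains(ppm)
    if mask.sum() < min_points:
        raise SpectralWindowError(
            f"noise window contains {int(mask.sum())} points; need >= {min_points}"
        )
    x = spec.values.real[mask]
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def apply_phase(spec: Spectrum, phi: float) -> Spectrum:
    """Multiply a spectrum by exp(i*phi) (helper for tests and simulation)."""
    return replace(spec, values=spec.values * np.exp(1j * phi))
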