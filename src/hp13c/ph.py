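"""Extracellular pH from dynamic hyperpolarized bicarbonate/CO2 spectra.

The measurement rests on the Henderson–Hasselbalch relation: with carbonic
anhydrase keeping the 13C label equilibrated between H13CO3- and 13CO2, the
signal ratio gives

    pH = pKa - log10( S(CO2) / S(HCO3-) ),            pKa = 6.17 by default.

The processing chain mirrors the acquisition it was designed for: spectra
acquired every second from 12 s after injection are summed over 12–39 s
(28 spectra at 1 s spacing), zero-order phased, quadratic-baseline
corrected, and the two resonances integrated over 123–127 ppm (CO2) and
156–163 ppm (HCO3-). An equilibration check on the per-spectrum ratio
series guards the key assumption that the ratio is time-invariant.

:class:`BicarbonatePHModel` wraps the chain in a model/results interface;
:func:`estimate_ph` is the one-call functional equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spectral import (
    FIDRecord,
    PpmWindow,
    SpectralAxis,
    Spectrum,
    estimate_noise_rms,
    fid_to_spectrum,
    integrate_window,
    quadratic_baseline_correct,
    zero_order_phase,
)

__all__ = [
    "CO2_WINDOW",
    "HCO3_WINDOW",
    "DynamicSeries",
    "SummedSpectrum",
    "EquilibrationReport",
    "PHResult",
    "BicarbonatePHModel",
    "sum_window",
    "equilibration_check",
    "co2_bicarb_ratio",
    "ratio_to_ph",
    "estimate_ph",
]

CO2_WINDOW = PpmWindow(123.0, 127.0)
HCO3_WINDOW = PpmWindow(156.0, 163.0)
# Signal-free region used for noise estimation (below the CO2 line).
DEFAULT_NOISE_WINDOW = PpmWindow(106.0, 118.0)
DEFAULT_PKA = 6.17


@dataclass
class DynamicSeries:
    """Time-stamped sequence of FIDs from the bicarbonate experiment.

    Timestamps must be strictly increasing and uniformly spaced (within
    1 ms); all FIDs share one spectral axis.
    """

    fids: list[FIDRecord]

    def __post_init__(self) -> None:
        if not self.fids:
            raise ValueError("DynamicSeries requires at least one FID")
        axis = self.fids[0].axis
        for fid in self.fids:
            if fid.axis != axis:
                raise ValueError("all FIDs in a series must share one SpectralAxis")
            if fid.timestamp_s is None:
                raise ValueError("every FID in a series needs a timestamp_s")
        ts = self.timestamps_s
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-3:
                raise ValueError("timestamps must be uniformly spaced (1 ms tolerance)")

    @property
    def axis(self) -> SpectralAxis:
        return self.fids[0].axis

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.fids], dtype=float)

    def __len__(self) -> int:
        return len(self.fids)


@dataclass(frozen=True)
class SummedSpectrum:
    spectrum: Spectrum
    n_summed: int
    t_lo_s: float
    t_hi_s: float


def sum_window(series: DynamicSeries, t_lo_s: float = 12.0, t_hi_s: float = 39.0) -> SummedSpectrum:
    """Sum FIDs with t_lo <= timestamp <= t_hi and Fourier transform.

    For a 1 s-spaced series starting at 12 s, the 12–39 s window selects
    exactly 28 spectra. Summation happens in the time domain; by linearity
    of the transform this equals summing the individual spectra.
    """
    selected = [f for f in series.fids if t_lo_s <= f.timestamp_s <= t_hi_s]
    if not selected:
        raise ValueError(
            f"no spectra with timestamps in [{t_lo_s}, {t_hi_s}] s "
            f"(series spans {series.timestamps_s[0]}–{series.timestamps_s[-1]} s)"
        )
    total = np.sum([f.samples for f in selected], axis=0)
    spec = fid_to_spectrum(FIDRecord(samples=total, axis=series.axis))
    return SummedSpectrum(spectrum=spec, n_summed=len(selected), t_lo_s=t_lo_s, t_hi_s=t_hi_s)


@dataclass
class EquilibrationReport:
    """Per-spectrum CO2/HCO3- ratios and the drift test on them.

    ``equilibrated`` is true when the 95% interval of the weighted
    regression slope contains zero, or when the fitted relative drift is
    below 10% per 10 s of the mean ratio.
    """

    times_s: np.ndarray
    ratios: np.ndarray
    co2_snr: np.ndarray
    slope_per_s: float
    slope_ci95: tuple[float, float]
    relative_drift_per_10s: float
    equilibrated: bool
    t_last_detectable_co2_s: float
    n_usable: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times_s, "ratio_co2_hco3": self.ratios, "co2_snr": self.co2_snr}
        )


def _per_spectrum_quantities(
    series: DynamicSeries,
    co2_window: PpmWindow,
    hco3_window: PpmWindow,
    noise_window: PpmWindow,
    baseline_margin_ppm: float,
) -> pd.DataFrame:
    rows = []
    excludes = [co2_window.dilate(baseline_margin_ppm), hco3_window.dilate(baseline_margin_ppm)]
    for fid in series.fids:
        spec = zero_order_phase(fid_to_spectrum(fid), [co2_window, hco3_window])
        spec = quadratic_baseline_correct(spec, excludes)
        noise = estimate_noise_rms(spec, noise_window, signal_windows=[co2_window, hco3_window])
        co2_i = integrate_window(spec, co2_window)
        hco3_i = integrate_window(spec, hco3_window)
        ppm = spec.axis.ppm
        co2_peak = float(spec.values.real[co2_window.contains(ppm)].max())
        rows.append(
            {
                "time_s": fid.timestamp_s,
                "co2_integral": co2_i,
                "hco3_integral": hco3_i,
                "co2_snr": co2_peak / noise if noise > 0 else np.inf,
            }
        )
    df = pd.DataFrame(rows)
    df["ratio_co2_hco3"] = df["co2_integral"] / df["hco3_integral"]
    return df


def equilibration_check(
    series: DynamicSeries,
    co2_window: PpmWindow = CO2_WINDOW,
    hco3_window: PpmWindow = HCO3_WINDOW,
    noise_window: PpmWindow = DEFAULT_NOISE_WINDOW,
    snr_threshold: float = 3.0,
    drift_tolerance_per_10s: float = 0.10,
    baseline_margin_ppm: float = 1.0,
) -> EquilibrationReport:
    """Test that the per-spectrum CO2/HCO3- ratio is constant in time.

    Uses spectra whose CO2 peak SNR exceeds ``snr_threshold`` (at least 5
    required), regresses ratio on time weighted by CO2 SNR^2, and accepts
    equilibration when the slope's 95% interval contains zero or the
    relative drift over 10 s is below ``drift_tolerance_per_10s``.
    """
    df = _per_spectrum_quantities(series, co2_window, hco3_window, noise_window, baseline_margin_ppm)
    usable = df[df["co2_snr"] > snr_threshold]
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} spectra have CO2 SNR > {snr_threshold}; "
            "at least 5 are needed for the equilibration check"
        )
    t = usable["time_s"].to_numpy()
    r = usable["ratio_co2_hco3"].to_numpy()
    w = usable["co2_snr"].to_numpy() ** 2
    x = sm.add_constant(t)
    fit = sm.WLS(r, x, weights=w).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    ci_lo, ci_hi = float(ci[1][0]), float(ci[1][1])
    mean_ratio = float(np.average(r, weights=w))
    rel_drift = abs(slope) * 10.0 / mean_ratio if mean_ratio != 0 else np.inf
    equilibrated = (ci_lo <= 0.0 <= ci_hi) or (rel_drift < drift_tolerance_per_10s)
    detectable = df[df["co2_snr"] > snr_threshold]["time_s"]
    return EquilibrationReport(
        times_s=df["time_s"].to_numpy(),
        ratios=df["ratio_co2_hco3"].to_numpy(),
        co2_snr=df["co2_snr"].to_numpy(),
        slope_per_s=slope,
        slope_ci95=(ci_lo, ci_hi),
        relative_drift_per_10s=rel_drift,
        equilibrated=bool(equilibrated),
        t_last_detectable_co2_s=float(detectable.max()),
        n_usable=int(len(usable)),
    )


def co2_bicarb_ratio(
    spec: Spectrum,
    co2_window: PpmWindow = CO2_WINDOW,
    hco3_window: PpmWindow = HCO3_WINDOW,
) -> float:
    """Ratio of the CO2 to the bicarbonate window integral.

    Expects a phased, baseline-corrected spectrum. A non-positive
    bicarbonate integral leaves the ratio (and pH) undefined and raises.
    """
    co2_i = integrate_window(spec, co2_window)
    hco3_i = integrate_window(spec, hco3_window)
    if hco3_i <= 0:
        raise ValueError(
            f"bicarbonate window integral is non-positive ({hco3_i:.3g}); pH undefined"
        )
    return co2_i / hco3_i


def ratio_to_ph(ratio_co2_hco3: float, pka: float = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch: pH = pKa - log10(S_CO2 / S_HCO3-)."""
    if ratio_co2_hco3 <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio_co2_hco3}")
    return pka - math.log10(ratio_co2_hco3)


@dataclass
class PHResult:
    """End product of the pH pipeline, with its full processing record.

    When the CO2 integral is at or below 3x its propagated noise the
    estimate is censored: ``ph`` then holds the lower bound implied by the
    3-sigma CO2 detection limit and ``censored`` is set.
    """

    ph: float
    censored: bool
    ratio_co2_hco3: float
    co2_integral: float
    hco3_integral: float
    co2_integral_noise: float
    pka: float
    n_summed: int
    phase_rad: float
    baseline_coeffs: np.ndarray | None
    equilibration: EquilibrationReport | None
    warnings: list[str] = field(default_factory=list)

    @property
    def ratio_hco3_co2(self) -> float:
        """The inverse orientation (bicarbonate over CO2), kept explicit."""
        return np.inf if self.ratio_co2_hco3 == 0 else 1.0 / self.ratio_co2_hco3

    def summary(self) -> str:
        lines = [
            "Bicarbonate/CO2 pH estimate",
            "---------------------------",
            f"summed spectra        : {self.n_summed}",
            f"CO2 integral          : {self.co2_integral:.6g} (noise {self.co2_integral_noise:.3g})",
            f"HCO3- integral        : {self.hco3_integral:.6g}",
            f"CO2/HCO3- ratio       : {self.ratio_co2_hco3:.5g}",
            f"pKa                   : {self.pka}",
            f"pH                    : {'>= ' if self.censored else ''}{self.ph:.3f}",
            f"zero-order phase (rad): {self.phase_rad:.4f}",
        ]
        if self.equilibration is not None:
            eq = self.equilibration
            lines.append(
                f"equilibrated          : {eq.equilibrated} "
                f"(slope {eq.slope_per_s:.3g}/s, 95% CI {eq.slope_ci95[0]:.3g}..{eq.slope_ci95[1]:.3g})"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class BicarbonatePHModel:
    """Extracellular pH model for a dynamic bicarbonate series.

    Parameters
    ----------
    series : DynamicSeries
        Serial FIDs with timestamps (seconds post-injection).
    pka : float
        Acid dissociation constant of the bicarbonate/CO2 couple.
    t_lo_s, t_hi_s : float
        Temporal summation window.
    co2_window, hco3_window : PpmWindow
        Integration windows.
    noise_window : PpmWindow
        Signal-free region for noise estimation.
    baseline_margin_ppm : float
        Dilation of the analysis windows when anchoring the baseline fit;
        defaults to three times the expected linewidth of an 8 Hz line.
    check_equilibration : bool
        Run the per-spectrum ratio drift check; a failed (or impossible)
        check downgrades to a warning on the result, never an exception.
    """

    def __init__(
        self,
        series: DynamicSeries,
        pka: float = DEFAULT_PKA,
        t_lo_s: float = 12.0,
        t_hi_s: float = 39.0,
        co2_window: PpmWindow = CO2_WINDOW,
        hco3_window: PpmWindow = HCO3_WINDOW,
        noise_window: PpmWindow = DEFAULT_NOISE_WINDOW,
        baseline_margin_ppm: float | None = None,
        expected_linewidth_hz: float = 8.0,
        check_equilibration: bool = True,
    ) -> None:
        self.series = series
        self.pka = pka
        self.t_lo_s = t_lo_s
        self.t_hi_s = t_hi_s
        self.co2_window = co2_window
        self.hco3_window = hco3_window
        self.noise_window = noise_window
        if baseline_margin_ppm is None:
            baseline_margin_ppm = (
                3.0 * expected_linewidth_hz / series.axis.spectrometer_freq_mhz
            )
        self.baseline_margin_ppm = baseline_margin_ppm
        self.check_equilibration = check_equilibration

    def fit(self) -> PHResult:
        warnings: list[str] = []
        equilibration: EquilibrationReport | None = None
        if self.check_equilibration:
            try:
                equilibration = equilibration_check(
                    self.series,
                    co2_window=self.co2_window,
                    hco3_window=self.hco3_window,
                    noise_window=self.noise_window,
                    baseline_margin_ppm=self.baseline_margin_ppm,
                )
                if not equilibration.equilibrated:
                    warnings.append(
                        "per-spectrum CO2/HCO3- ratio drifts with time; the label may "
                        "not be equilibrated and the pH estimate may be biased"
                    )
            except ValueError as exc:
                warnings.append(f"equilibration check not possible: {exc}")

        summed = sum_window(self.series, self.t_lo_s, self.t_hi_s)
        spec = zero_order_phase(summed.spectrum, [self.co2_window, self.hco3_window])
        excludes = [
            self.co2_window.dilate(self.baseline_margin_ppm),
            self.hco3_window.dilate(self.baseline_margin_ppm),
        ]
        spec = quadratic_baseline_correct(spec, excludes)

        noise_rms = estimate_noise_rms(
            spec, self.noise_window, signal_windows=[self.co2_window, self.hco3_window]
        )
        co2_i = integrate_window(spec, self.co2_window)
        hco3_i = integrate_window(spec, self.hco3_window)
        if hco3_i <= 0:
            raise ValueError(
                f"bicarbonate window integral is non-positive ({hco3_i:.3g}); pH undefined"
            )
        # Propagated noise of a trapezoidal window integral over N bins.
        bin_ppm = spec.axis.ppm_bin_width
        n_bins = self.co2_window.width / bin_ppm
        co2_noise = noise_rms * bin_ppm * math.sqrt(n_bins)

        if co2_i <= 3.0 * co2_noise:
            # CO2 at/below the detection limit: report a pH lower bound.
            ratio_ub = 3.0 * co2_noise / hco3_i
            ph = ratio_to_ph(ratio_ub, self.pka)
            warnings.append(
                "CO2 integral is at or below its 3-sigma detection limit; "
                "pH is reported as a lower bound"
            )
            ratio = max(co2_i, 0.0) / hco3_i
            censored = True
        else:
            ratio = co2_i / hco3_i
            ph = ratio_to_ph(ratio, self.pka)
            censored = False

        return PHResult(
            ph=ph,
            censored=censored,
            ratio_co2_hco3=ratio,
            co2_integral=co2_i,
            hco3_integral=hco3_i,
            co2_integral_noise=co2_noise,
            pka=self.pka,
            n_summed=summed.n_summed,
            phase_rad=spec.phase_applied_rad,
            baseline_coeffs=spec.baseline_coeffs,
            equilibration=equilibration,
            warnings=warnings,
        )

    def per_spectrum_frame(self) -> pd.DataFrame:
        """Per-spectrum integrals and ratios (the dynamic ratio curve)."""
        return _per_spectrum_quantities(
            self.series, self.co2_window, self.hco3_window, self.noise_window,
            self.baseline_margin_ppm,
        )


def estimate_ph(series: DynamicSeries, **kwargs) -> PHResult:
    """One-call pH estimate: ``BicarbonatePHModel(series, **kwargs).fit()``."""
    return BicarbonatePHModel(series, **kwargs).fit()
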