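"""Seeded generators for every input the analysis pipeline consumes.

Nothing here is a test fixture: these generators define the study conditions
under which the pipeline is exercised — a 32x32 MRSI grid of four-resonance
13C FIDs over a 40x40 mm^2 field of view, serial 1 s-interval bicarbonate/CO2
spectra (6000 Hz bandwidth, 1024 points) with a ~10 s polarization half-life,
and longitudinal calliper/clinical-score tables for a complete Freund's
adjuvant (CFA) paw-inflammation study with n paws per condition.

All generators are pure functions of their configuration (seed included):
identical configs produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon

from .spectral import FIDRecord, PpmWindow, Resonance, SpectralAxis, model_fid

__all__ = [
    "PYRUVATE_PPM",
    "LACTATE_PPM",
    "CO2_WINDOW",
    "HCO3_WINDOW",
    "MRSI_AXIS",
    "BICARB_AXIS",
    "PawRegion",
    "MRSIPhantomConfig",
    "BicarbSeriesConfig",
    "PawStudyConfig",
    "MRSIPhantom",
    "noise_sd_for_peak_snr",
    "disk_polygon",
    "simulate_voxel_fid",
    "simulate_mrsi_phantom",
    "simulate_bicarbonate_series",
    "simulate_paw_study",
]

# Nominal chemical shifts (ppm). Pyruvate and lactate are the two quantified
# lines; the hydrate- and alanine-like lines are the small auxiliary
# resonances that make the voxel model four lines deep.
PYRUVATE_PPM = 173.0
LACTATE_PPM = 185.0
PYRUVATE_HYDRATE_PPM = 181.0
ALANINE_PPM = 178.0
FOUR_RESONANCE_SHIFTS_PPM = (PYRUVATE_PPM, LACTATE_PPM, PYRUVATE_HYDRATE_PPM, ALANINE_PPM)

# Integration windows for the bicarbonate experiment (ppm).
CO2_WINDOW = PpmWindow(123.0, 127.0)
HCO3_WINDOW = PpmWindow(156.0, 163.0)

LARMOR_13C_7T_MHZ = 75.4

# Carriers sit midway between the lines each experiment quantifies.
MRSI_AXIS = SpectralAxis(
    n_points=256, bandwidth_hz=6000.0, spectrometer_freq_mhz=LARMOR_13C_7T_MHZ,
    carrier_ppm=179.0,
)
BICARB_AXIS = SpectralAxis(
    n_points=1024, bandwidth_hz=6000.0, spectrometer_freq_mhz=LARMOR_13C_7T_MHZ,
    carrier_ppm=145.0,
)


def noise_sd_for_peak_snr(
    amplitude: float,
    snr: float,
    axis: SpectralAxis,
    ref_linewidth_hz: float = 50.0,
) -> float:
    """Time-domain complex noise SD giving a target frequency-domain SNR.

    SNR follows the MRSI quality-control convention: the peak height of a
    ``ref_linewidth_hz``-wide absorption Lorentzian of time-domain amplitude
    ``amplitude`` — ``A / (pi * fwhm)`` under the dwell-scaled FT — divided by
    the RMS noise of the real spectrum. White complex time-domain noise of
    per-component SD ``sigma`` transforms to real-part RMS
    ``sigma * sqrt(n) * dwell``.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    peak_height = amplitude / (np.pi * ref_linewidth_hz)
    sigma_f = peak_height / snr
    return sigma_f / (math.sqrt(axis.n_points) * axis.dwell_s)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_voxel_fid(
    resonances: Sequence[Resonance],
    axis: SpectralAxis,
    noise_sd: float,
    seed,
) -> FIDRecord:
    """Model FID plus i.i.d. complex white Gaussian noise.

    ``noise_sd`` is the standard deviation of the real and of the imaginary
    part of each time-domain sample. Deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = _rng(seed)
    fid = model_fid(resonances, axis)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(2, axis.n_points))
        fid.samples = fid.samples + noise[0] + 1j * noise[1]
    return fid


# ---------------------------------------------------------------------------
# MRSI phantom
# ---------------------------------------------------------------------------

def disk_polygon(centre_mm: tuple[float, float], radius_mm: float, n_vertices: int = 64) -> list[tuple[float, float]]:
    """Regular-polygon approximation of a disk, as (x, y) mm vertices."""
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return [
        (centre_mm[0] + radius_mm * math.cos(a), centre_mm[1] + radius_mm * math.sin(a))
        for a in th
    ]


@dataclass(frozen=True)
class PawRegion:
    """One paw-shaped region of the phantom.

    ``ratio_mean`` is the regional ground-truth lactate/pyruvate ratio;
    per-voxel true ratios are jittered around it with SD ``ratio_jitter_sd``
    (draws are re-centred so the regional mean equals ``ratio_mean`` exactly,
    then clipped at zero).
    """

    polygon_mm: tuple[tuple[float, float], ...]
    ratio_mean: float
    ratio_jitter_sd: float = 0.1
    pyruvate_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio_mean < 0:
            raise ValueError("ratio_mean must be >= 0")
        if self.ratio_jitter_sd < 0:
            raise ValueError("ratio_jitter_sd must be >= 0")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon_mm)


@dataclass(frozen=True)
class MRSIPhantomConfig:
    """Conditions of the synthetic MRSI acquisition.

    Defaults mirror the in vivo protocol being emulated: 32x32 voxels over a
    40x40 mm^2 field of view with a 128x128 proton reference, four Lorentzian
    lines per in-region voxel (pyruvate 173 ppm, lactate 185 ppm plus two
    small auxiliary lines), and white complex time-domain noise set so a
    unit-amplitude pyruvate line has peak SNR 20 under the 50 Hz-linewidth
    convention used by the quality-control gate.
    """

    regions: tuple[PawRegion, ...] = (
        PawRegion(tuple(disk_polygon((12.0, 20.0), 6.0)), ratio_mean=0.74),
        PawRegion(tuple(disk_polygon((28.0, 20.0), 6.0)), ratio_mean=0.30),
    )
    grid_shape: tuple[int, int] = (32, 32)
    fov_mm: tuple[float, float] = (40.0, 40.0)
    proton_matrix: tuple[int, int] = (128, 128)
    shifts_ppm: tuple[float, float, float, float] = FOUR_RESONANCE_SHIFTS_PPM
    linewidth_hz: tuple[float, float, float, float] = (30.0, 30.0, 30.0, 30.0)
    aux_amplitude_fractions: tuple[float, float] = (0.08, 0.05)
    axis: SpectralAxis = MRSI_AXIS
    noise_sd: float | None = None  # None -> pyruvate peak SNR 20 at amplitude 1
    pyruvate_peak_snr: float = 20.0
    slice_thickness_mm: float = 8.0
    seed: int = 0

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            if self.noise_sd < 0:
                raise ValueError("noise_sd must be >= 0")
            return self.noise_sd
        return noise_sd_for_peak_snr(1.0, self.pyruvate_peak_snr, self.axis)


@dataclass
class MRSIPhantom:
    """Output bundle of :func:`simulate_mrsi_phantom`."""

    grid: "MRSIGrid"  # noqa: F821 - forward ref, defined in hp13c.mrsi
    true_ratio: np.ndarray  # NaN outside all regions
    region_masks: list[np.ndarray]
    proton_image: np.ndarray
    config: MRSIPhantomConfig


def simulate_mrsi_phantom(cfg: MRSIPhantomConfig) -> MRSIPhantom:
    """Simulate an MRSI grid with paw regions of known lactate/pyruvate ratio.

    In-region voxels carry the region's pyruvate amplitude, lactate equal to
    the (jittered) true ratio times pyruvate, and two small auxiliary lines;
    out-of-region voxels are noise only. The proton reference image is a
    softened binary rendering of the region masks.
    """
    from .mrsi import MRSIGrid  # local import to avoid a cycle

    polys = [r.shapely() for r in cfg.regions]
    for p in polys:
        if not p.is_valid or p.area <= 0:
            raise ValueError("phantom region polygon is degenerate")
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersection(polys[j]).area > 0:
                raise ValueError(f"phantom regions {i} and {j} overlap")

    n_rows, n_cols = cfg.grid_shape
    dx = cfg.fov_mm[0] / n_cols
    dy = cfg.fov_mm[1] / n_rows
    noise_sd = cfg.resolved_noise_sd()
    rng = _rng(cfg.seed)

    region_masks = []
    for p in polys:
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        for r in range(n_rows):
            for c in range(n_cols):
                mask[r, c] = p.covers(Point((c + 0.5) * dx, (r + 0.5) * dy))
        region_masks.append(mask)

    true_ratio = np.full((n_rows, n_cols), np.nan)
    for region, mask in zip(cfg.regions, region_masks):
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        jitter = rng.normal(0.0, region.ratio_jitter_sd, size=n_vox)
        ratios = np.clip(region.ratio_mean + (jitter - jitter.mean()), 0.0, None)
        true_ratio[mask] = ratios

    f_hyd, f_ala = cfg.aux_amplitude_fractions
    fids = np.empty((n_rows, n_cols), dtype=object)
    for r in range(n_rows):
        for c in range(n_cols):
            resonances: list[Resonance] = []
            for region, mask in zip(cfg.regions, region_masks):
                if mask[r, c]:
                    a_pyr = region.pyruvate_amplitude
                    ratio = float(true_ratio[r, c])
                    amps = (a_pyr, ratio * a_pyr, f_hyd * a_pyr, f_ala * a_pyr)
                    resonances = [
                        Resonance(s, a, lw)
                        for s, a, lw in zip(cfg.shifts_ppm, amps, cfg.linewidth_hz)
                    ]
                    break
            fids[r, c] = simulate_voxel_fid(resonances, cfg.axis, noise_sd, rng)

    grid = MRSIGrid(
        fids=fids,
        axis=cfg.axis,
        fov_mm=cfg.fov_mm,
        slice_thickness_mm=cfg.slice_thickness_mm,
    )

    pm_rows, pm_cols = cfg.proton_matrix
    px = cfg.fov_mm[0] / pm_cols
    py = cfg.fov_mm[1] / pm_rows
    xs = ((np.arange(pm_cols) + 0.5) * px)[None, :].repeat(pm_rows, axis=0)
    ys = ((np.arange(pm_rows) + 0.5) * py)[:, None].repeat(pm_cols, axis=1)
    proton = np.zeros((pm_rows, pm_cols))
    for p in polys:
        proton[shapely.contains_xy(p, xs.ravel(), ys.ravel()).reshape(pm_rows, pm_cols)] = 1.0
    proton = gaussian_filter(proton, sigma=1.0)

    return MRSIPhantom(
        grid=grid,
        true_ratio=true_ratio,
        region_masks=region_masks,
        proton_image=proton,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Dynamic bicarbonate series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BicarbSeriesConfig:
    """Conditions of the synthetic dynamic bicarbonate/CO2 acquisition.

    Serial pulse-acquire spectra (6000 Hz bandwidth, 1024 points, 10 deg
    flip) every second from 12 s after injection. The CO2/HCO3- amplitude
    ratio is fixed at ``10**(pka - ph_true)`` at every time point (the
    carbonic-anhydrase-equilibrated regime); both lines decay together with
    the polarization half-life and the per-pulse cos(flip) loss. Setting
    ``equilibration_tau_s`` switches on a pre-equilibrium mode in which the
    ratio approaches its equilibrium value as ``1 - exp(-t/tau)``, for
    exercising the equilibration check's rejection branch.

    The default noise level (per-component time-domain SD, for unit initial
    bicarbonate amplitude) is set so the CO2 window integral of the 28-
    spectrum sum has SNR near 100 at pH ~7.3 — a regime in which the minor
    resonance is cleanly quantifiable, as in the summed in vivo spectra the
    pipeline emulates.
    """

    ph_true: float = 7.23
    pka: float = 6.17
    t_start_s: float = 12.0
    dt_s: float = 1.0
    n_spectra: int = 32
    polarization_halflife_s: float = 10.0
    flip_angle_deg: float = 10.0
    bicarb_amplitude0: float = 1.0
    linewidth_hz: float = 8.0
    noise_sd: float = 4.0e-3
    equilibration_tau_s: float | None = None
    axis: SpectralAxis = BICARB_AXIS
    hco3_ppm: float = HCO3_WINDOW.centre  # 159.5
    co2_ppm: float = CO2_WINDOW.centre  # 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (6.0 <= self.ph_true <= 8.0):
            raise ValueError(f"ph_true must be in [6.0, 8.0], got {self.ph_true}")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_bicarbonate_series(cfg: BicarbSeriesConfig) -> "DynamicSeries":  # noqa: F821
    """Simulate the dynamic H13CO3-/13CO2 spectral series.

    Spectrum n (timestamp ``t_start + n*dt``) contains the bicarbonate and
    CO2 resonances at the centres of their integration windows, with common
    decay ``exp(-(t - t_start)/tau) * cos(flip)**n`` and amplitude ratio
    ``10**(pka - ph_true)`` (optionally approached exponentially in the
    pre-equilibrium mode).
    """
    from .ph import DynamicSeries  # local import to avoid a cycle

    rng = _rng(cfg.seed)
    tau = cfg.polarization_halflife_s / math.log(2.0)
    cos_flip = math.cos(math.radians(cfg.flip_angle_deg))
    ratio_eq = 10.0 ** (cfg.pka - cfg.ph_true)

    fids = []
    for n in range(cfg.n_spectra):
        t = cfg.t_start_s + n * cfg.dt_s
        decay = math.exp(-(t - cfg.t_start_s) / tau) * cos_flip**n
        a_hco3 = cfg.bicarb_amplitude0 * decay
        if cfg.equilibration_tau_s is None:
            ratio = ratio_eq
        else:
            ratio = ratio_eq * (1.0 - math.exp(-t / cfg.equilibration_tau_s))
        resonances = [
            Resonance(cfg.hco3_ppm, a_hco3, cfg.linewidth_hz),
            Resonance(cfg.co2_ppm, ratio * a_hco3, cfg.linewidth_hz),
        ]
        fid = simulate_voxel_fid(resonances, cfg.axis, cfg.noise_sd, rng)
        fid.timestamp_s = t
        fid.flip_angle_deg = cfg.flip_angle_deg
        fids.append(fid)
    return DynamicSeries(fids=fids)


# ---------------------------------------------------------------------------
# Paw morphometry study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PawStudyConfig:
    """Conditions of the synthetic CFA paw-swelling study.

    Each mouse receives CFA in one hind paw and vehicle (PBS) in the other;
    ankle and footpad diameters (calliper, mm) and an ordinal clinical score
    (0 normal, 1 slight swelling/erythema, 2 pronounced swelling,
    3 ankylosis) are recorded daily. Effect profiles are per-day additive
    shifts of the CFA side relative to the PBS baseline.
    """

    n_mice: int = 5
    days: tuple[int, ...] = (1, 2, 3, 4, 5)
    ankle_baseline_mm: float = 3.2
    footpad_baseline_mm: float = 2.0
    cfa_ankle_effect_mm: tuple[float, ...] = (0.8, 1.0, 1.1, 1.2, 1.2)
    cfa_footpad_effect_mm: tuple[float, ...] = (0.6, 0.8, 0.9, 1.0, 1.0)
    cfa_score_latent: tuple[float, ...] = (1.0, 1.5, 2.0, 2.0, 2.5)
    measurement_noise_mm: float = 0.1
    score_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cfa_ankle_effect_mm", "cfa_footpad_effect_mm", "cfa_score_latent"):
            if len(getattr(self, name)) != len(self.days):
                raise ValueError(f"{name} must have one entry per day")


def simulate_paw_study(cfg: PawStudyConfig) -> pd.DataFrame:
    """Long-format table (mouse, day, side, ankle_mm, footpad_mm, score)."""
    rng = _rng(cfg.seed)
    rows = []
    for mouse in range(1, cfg.n_mice + 1):
        for i, day in enumerate(cfg.days):
            for side in ("CFA", "PBS"):
                cfa = side == "CFA"
                ankle = cfg.ankle_baseline_mm + (cfg.cfa_ankle_effect_mm[i] if cfa else 0.0)
                footpad = cfg.footpad_baseline_mm + (
                    cfg.cfa_footpad_effect_mm[i] if cfa else 0.0
                )
                ankle += rng.normal(0.0, cfg.measurement_noise_mm)
                footpad += rng.normal(0.0, cfg.measurement_noise_mm)
                latent = (cfg.cfa_score_latent[i] if cfa else 0.0) + rng.normal(
                    0.0, cfg.score_noise
                )
                score = int(np.clip(round(latent), 0, 3))
                rows.append(
                    {
                        "mouse": mouse,
                        "day": day,
                        "side": side,
                        "ankle_mm": max(ankle, 0.1),
                        "footpad_mm": max(footpad, 0.1),
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)
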