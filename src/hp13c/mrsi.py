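"""Voxelwise four-resonance fitting and lactate/pyruvate ratio mapping.

Each voxel of a 13C MRSI acquisition holds a free induction decay that is
modelled as four Lorentzian resonances — [1-13C]pyruvate (173 ppm),
[1-13C]lactate (185 ppm) and two small auxiliary lines — fitted by least
squares in the time domain over amplitudes, shifts, linewidths and a common
zero-order phase. The fitted amplitude ratio lactate/pyruvate is the map
value; a quality-control gate keeps voxels whose pyruvate amplitude,
expressed as the peak height of a 50 Hz-linewidth absorption line, exceeds
11 times the RMS spectral noise (strictly); region-of-interest selection
keeps voxels whose centres fall inside a polygon drawn on the proton
reference image.

The fit uses variable projection: for given shifts, linewidths and phase
the non-negative amplitudes solve a linear least-squares problem (NNLS),
and only the nine nonlinear parameters are iterated. Initialisation is
deterministic (nominal shifts, 30 Hz linewidths, magnitude-spectrum peak
amplitudes, phase of the largest peak) — no random restarts.

:class:`LactatePyruvateModel` is the model/results entry point; the free
functions below are the individual pipeline stages it composes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.optimize import least_squares, nnls
from shapely.geometry import Polygon

from .spectral import (
    FIDRecord,
    PpmWindow,
    Resonance,
    SpectralAxis,
    Spectrum,
    estimate_noise_rms,
    fid_to_spectrum,
)

__all__ = [
    "MRSIGrid",
    "ROIPolygon",
    "VoxelFitConfig",
    "VoxelFit",
    "RatioMap",
    "VoxelGroupTest",
    "LactatePyruvateModel",
    "LactatePyruvateResults",
    "fit_voxel",
    "lactate_pyruvate_ratio",
    "qc_mask",
    "select_roi_voxels",
    "ratio_map",
    "compare_voxel_groups",
]

QC_REF_LINEWIDTH_HZ = 50.0
QC_SNR_THRESHOLD = 11.0


@dataclass
class MRSIGrid:
    """Spatial grid of FIDs with geometry mapping to the proton frame.

    Voxel (r, c) has its centre at ``origin + ((c+0.5)*fov_x/n_cols,
    (r+0.5)*fov_y/n_rows)`` mm, row-major with 0-based indices — the proton
    image pixel convention at coarser pitch.
    """

    fids: np.ndarray  # 2D object array of FIDRecord
    axis: SpectralAxis
    fov_mm: tuple[float, float] = (40.0, 40.0)
    slice_thickness_mm: float = 8.0
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids, dtype=object)
        if self.fids.ndim != 2:
            raise ValueError("fids must be a 2D array of FIDRecord")
        for fid in self.fids.ravel():
            if fid.axis != self.axis:
                raise ValueError("all FIDs in the grid must share the grid axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fids.shape

    def voxel_centre_mm(self, r: int, c: int) -> tuple[float, float]:
        n_rows, n_cols = self.shape
        return (
            self.origin_mm[0] + (c + 0.5) * self.fov_mm[0] / n_cols,
            self.origin_mm[1] + (r + 0.5) * self.fov_mm[1] / n_rows,
        )


@dataclass(frozen=True)
class ROIPolygon:
    """Simple closed polygon in proton-frame mm coordinates."""

    vertices_mm: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices_mm) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        p = Polygon(self.vertices_mm)
        if not p.is_valid or p.area <= 0:
            raise ValueError("ROI polygon is degenerate (self-intersecting or zero area)")

    def shapely(self) -> Polygon:
        return Polygon(self.vertices_mm)


@dataclass(frozen=True)
class VoxelFitConfig:
    """Initialisation and constraints of the four-resonance voxel fit."""

    nominal_shifts_ppm: tuple[float, ...] = (173.0, 185.0, 181.0, 178.0)
    labels: tuple[str, ...] = ("pyruvate", "lactate", "pyruvate_hydrate", "alanine")
    shift_tolerance_ppm: float = 1.5
    linewidth_bounds_hz: tuple[float, float] = (5.0, 200.0)
    init_linewidth_hz: float = 30.0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.nominal_shifts_ppm):
            raise ValueError("labels and nominal_shifts_ppm must align")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class VoxelFit:
    """Result of fitting one voxel: four resonances plus diagnostics."""

    resonances: list[Resonance]
    config: VoxelFitConfig
    residual_rms: float
    converged: bool
    noise_rms: float
    phase_rad: float

    def amplitude(self, label: str) -> float:
        return self.resonances[self.config.index_of(label)].amplitude

    def shift(self, label: str) -> float:
        return self.resonances[self.config.index_of(label)].shift_ppm


def _design_matrix(axis: SpectralAxis, shifts, linewidths, phase) -> np.ndarray:
    t = axis.times_s
    cols = []
    for s, lw in zip(shifts, linewidths):
        f = axis.ppm_to_hz(s)
        g = np.exp(1j * phase) * np.exp((2j * np.pi * f - np.pi * lw) * t)
        cols.append(np.concatenate([g.real, g.imag]))
    return np.column_stack(cols)


def fit_voxel(fid: FIDRecord, config: VoxelFitConfig = VoxelFitConfig()) -> VoxelFit:
    """Least-squares four-resonance fit of one voxel FID.

    Minimises ``sum |fid - model|^2`` over non-negative amplitudes, shifts
    within +/- ``shift_tolerance_ppm`` of the nominal positions, linewidths
    within ``linewidth_bounds_hz`` and one common phase. Amplitudes are
    eliminated by non-negative linear least squares at each step of the
    nonlinear iteration. Never raises on non-convergence: the best
    parameters so far are returned with ``converged=False``.
    """
    if fid.axis.n_points < 64:
        raise ValueError("voxel fit requires at least 64 FID points")
    axis = fid.axis
    k = len(config.nominal_shifts_ppm)
    y = np.concatenate([fid.samples.real, fid.samples.imag])

    # --- deterministic initialisation from the magnitude spectrum
    spec = fid_to_spectrum(fid)
    mag = np.abs(spec.values)
    ppm = axis.ppm
    init_amp = np.empty(k)
    peak_vals = np.empty(k)
    for j, s in enumerate(config.nominal_shifts_ppm):
        sel = np.abs(ppm - s) <= config.shift_tolerance_ppm
        if not sel.any():
            raise ValueError(
                f"nominal shift {s} ppm (+/- {config.shift_tolerance_ppm}) is outside the axis"
            )
        peak = mag[sel].max()
        peak_vals[j] = peak
        init_amp[j] = peak * np.pi * config.init_linewidth_hz
    j_max = int(np.argmax(peak_vals))
    sel = np.abs(ppm - config.nominal_shifts_ppm[j_max]) <= config.shift_tolerance_ppm
    idx = np.flatnonzero(sel)[np.argmax(mag[sel])]
    init_phase = float(np.angle(spec.values[idx]))

    lw_lo, lw_hi = config.linewidth_bounds_hz
    x0 = np.concatenate(
        [np.zeros(k), np.full(k, float(np.clip(config.init_linewidth_hz, lw_lo, lw_hi))), [init_phase]]
    )
    lb = np.concatenate([np.full(k, -config.shift_tolerance_ppm), np.full(k, lw_lo), [init_phase - np.pi]])
    ub = np.concatenate([np.full(k, config.shift_tolerance_ppm), np.full(k, lw_hi), [init_phase + np.pi]])

    nominal = np.asarray(config.nominal_shifts_ppm)

    def solve_amplitudes(x):
        shifts = nominal + x[:k]
        lws = x[k : 2 * k]
        m = _design_matrix(axis, shifts, lws, x[2 * k])
        amps, _ = nnls(m, y)
        return amps, m

    def residuals(x):
        amps, m = solve_amplitudes(x)
        return m @ amps - y

    converged = True
    try:
        sol = least_squares(
            residuals, x0, bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        x = sol.x
        converged = bool(sol.status > 0)
    except Exception:
        x = x0
        converged = False

    amps, m = solve_amplitudes(x)
    res = m @ amps - y
    phase = float(x[2 * k])
    resonances = [
        Resonance(
            shift_ppm=float(nominal[j] + x[j]),
            amplitude=float(amps[j]),
            linewidth_hz=float(x[k + j]),
            phase_rad=phase,
        )
        for j in range(k)
    ]
    noise_windows = _default_noise_window(axis, config)
    try:
        noise = estimate_noise_rms(spec, noise_windows)
    except Exception:
        noise = float("nan")
    return VoxelFit(
        resonances=resonances,
        config=config,
        residual_rms=float(np.sqrt(np.mean(res**2))),
        converged=converged,
        noise_rms=noise,
        phase_rad=phase,
    )


def _default_noise_window(axis: SpectralAxis, config: VoxelFitConfig) -> PpmWindow:
    """Signal-free window in the axis tail, away from all nominal lines."""
    lo, hi = axis.ppm_range
    margin = config.shift_tolerance_ppm + 3.0
    below = min(config.nominal_shifts_ppm) - margin
    above = max(config.nominal_shifts_ppm) + margin
    if below - lo >= hi - above:
        return PpmWindow(lo, below)
    return PpmWindow(above, hi)


def lactate_pyruvate_ratio(fit: VoxelFit) -> float:
    """Fitted lactate amplitude over fitted pyruvate amplitude.

    Scale-invariant: multiplying the FID by any c > 0 leaves it unchanged.
    A zero pyruvate amplitude leaves the ratio undefined (NaN).
    """
    pyr = fit.amplitude("pyruvate")
    if pyr <= 0:
        return float("nan")
    return fit.amplitude("lactate") / pyr


def qc_snr(fit_or_amplitude, noise_rms: float) -> float:
    """Pyruvate SNR under the 50 Hz-linewidth peak-height convention."""
    if noise_rms <= 0:
        raise ValueError("noise_rms must be > 0 for the QC gate")
    amp = (
        fit_or_amplitude.amplitude("pyruvate")
        if isinstance(fit_or_amplitude, VoxelFit)
        else float(fit_or_amplitude)
    )
    return amp / (np.pi * QC_REF_LINEWIDTH_HZ) / noise_rms


def qc_mask(
    fits: dict[tuple[int, int], VoxelFit],
    noise_rms: float,
    shape: tuple[int, int],
    snr_threshold: float = QC_SNR_THRESHOLD,
) -> np.ndarray:
    """Boolean map of voxels whose pyruvate SNR strictly exceeds the gate.

    The fitted pyruvate amplitude is converted to the peak height of a
    50 Hz-linewidth absorption Lorentzian (A / (pi*50) under the dwell-
    scaled FT) and compared against ``snr_threshold`` times the RMS noise;
    a voxel sitting exactly at the threshold is excluded.
    """
    if noise_rms <= 0:
        raise ValueError("noise_rms must be > 0 for the QC gate")
    mask = np.zeros(shape, dtype=bool)
    for (r, c), fit in fits.items():
        mask[r, c] = qc_snr(fit, noise_rms) > snr_threshold
    return mask


def select_roi_voxels(grid: MRSIGrid, roi: ROIPolygon) -> np.ndarray:
    """Voxels whose centre lies inside the ROI polygon (boundary inclusive)."""
    poly = roi.shapely()
    n_rows, n_cols = grid.shape
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = grid.voxel_centre_mm(r, c)
            mask[r, c] = bool(shapely.covers(poly, shapely.points(x, y)))
    return mask


@dataclass
class RatioMap:
    """Per-voxel lactate/pyruvate ratios with QC and ROI masks."""

    ratio: np.ndarray
    qc_mask: np.ndarray
    roi_mask: np.ndarray
    snr: np.ndarray

    @property
    def displayed(self) -> np.ndarray:
        """Ratios masked to QC-passing voxels (display convention)."""
        out = np.where(self.qc_mask, self.ratio, np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_rows, n_cols = self.ratio.shape
        for r in range(n_rows):
            for c in range(n_cols):
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "ratio": self.ratio[r, c],
                        "snr": self.snr[r, c],
                        "qc_pass": bool(self.qc_mask[r, c]),
                        "in_roi": bool(self.roi_mask[r, c]),
                    }
                )
        return pd.DataFrame(rows)


def ratio_map(
    grid: MRSIGrid,
    fits: dict[tuple[int, int], VoxelFit],
    roi: ROIPolygon | None,
    noise_rms: float,
    snr_threshold: float = QC_SNR_THRESHOLD,
) -> RatioMap:
    """Assemble the ratio map, QC mask and ROI mask from per-voxel fits."""
    shape = grid.shape
    ratio = np.full(shape, np.nan)
    snr = np.full(shape, np.nan)
    for (r, c), fit in fits.items():
        ratio[r, c] = lactate_pyruvate_ratio(fit)
        snr[r, c] = qc_snr(fit, noise_rms)
    qc = qc_mask(fits, noise_rms, shape, snr_threshold)
    roi_m = (
        select_roi_voxels(grid, roi) if roi is not None else np.ones(shape, dtype=bool)
    )
    return RatioMap(ratio=ratio, qc_mask=qc, roi_mask=roi_m, snr=snr)


@dataclass(frozen=True)
class VoxelGroupTest:
    """Two-sample comparison of voxel ratio groups."""

    t: float
    df: float
    p_two_sided: float
    p_one_sided_greater: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def compare_voxel_groups(
    ratios_a: Sequence[float], ratios_b: Sequence[float], equal_var: bool = False
) -> VoxelGroupTest:
    """Welch (default) two-sample t-test of voxel ratio groups, uncorrected.

    Group a is conventionally the inflamed paw, group b the pooled
    non-inflamed voxels; ``p_one_sided_greater`` tests mean_a > mean_b.
    No multiple-comparison correction is applied.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 voxels")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    df = float(res.df)
    p_two = float(res.pvalue)
    p_greater = float(stats.t.sf(t, df))
    return VoxelGroupTest(
        t=t,
        df=df,
        p_two_sided=p_two,
        p_one_sided_greater=p_greater,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )


class LactatePyruvateModel:
    """Voxelwise lactate/pyruvate model for an MRSI grid.

    Parameters
    ----------
    grid : MRSIGrid
        The spectroscopic imaging data.
    roi : ROIPolygon, optional
        Region of interest in proton-frame mm; when given, only voxels
        whose centres fall inside it are fitted (``voxels="all"`` fits the
        whole grid).
    fit_config : VoxelFitConfig
        Constraints and initialisation of the per-voxel fit.
    snr_threshold : float
        QC gate on pyruvate SNR (strictly greater-than).
    voxels : {"roi", "all"}
        Which voxels to fit.
    """

    def __init__(
        self,
        grid: MRSIGrid,
        roi: ROIPolygon | None = None,
        fit_config: VoxelFitConfig = VoxelFitConfig(),
        snr_threshold: float = QC_SNR_THRESHOLD,
        voxels: str = "roi",
    ) -> None:
        if voxels not in ("roi", "all"):
            raise ValueError("voxels must be 'roi' or 'all'")
        self.grid = grid
        self.roi = roi
        self.fit_config = fit_config
        self.snr_threshold = snr_threshold
        self.voxels = voxels

    def fit(self) -> "LactatePyruvateResults":
        roi_mask = (
            select_roi_voxels(self.grid, self.roi)
            if self.roi is not None
            else np.ones(self.grid.shape, dtype=bool)
        )
        targets = (
            np.argwhere(roi_mask) if self.voxels == "roi" else np.argwhere(np.ones(self.grid.shape, bool))
        )
        fits: dict[tuple[int, int], VoxelFit] = {}
        for r, c in targets:
            fits[(int(r), int(c))] = fit_voxel(self.grid.fids[r, c], self.fit_config)
        noise_values = [f.noise_rms for f in fits.values() if np.isfinite(f.noise_rms)]
        if not noise_values:
            raise ValueError("no voxel yielded a finite noise estimate")
        noise_rms = float(np.median(noise_values))
        rmap = ratio_map(self.grid, fits, self.roi, noise_rms, self.snr_threshold)
        return LactatePyruvateResults(
            model=self, fits=fits, noise_rms=noise_rms, map=rmap
        )


@dataclass
class LactatePyruvateResults:
    """Fitted ratio map plus per-voxel fits and diagnostics."""

    model: LactatePyruvateModel
    fits: dict[tuple[int, int], VoxelFit]
    noise_rms: float
    map: RatioMap

    def ratios(self, qc: bool = True, roi: bool = True) -> np.ndarray:
        """Fitted ratios of the selected voxels (1D, NaN-free)."""
        mask = np.ones(self.map.ratio.shape, dtype=bool)
        if qc:
            mask &= self.map.qc_mask
        if roi:
            mask &= self.map.roi_mask
        vals = self.map.ratio[mask]
        return vals[np.isfinite(vals)]

    def mean_ratio(self, qc: bool = True, roi: bool = True) -> float:
        vals = self.ratios(qc=qc, roi=roi)
        if len(vals) == 0:
            return float("nan")
        return float(vals.mean())

    def compare_to(self, other: "LactatePyruvateResults | Sequence[float]", qc: bool = False) -> VoxelGroupTest:
        """Welch comparison of this map's ROI voxels against another group.

        Quantitative comparison uses all ROI voxels by default (the QC gate
        is a display convention); pass ``qc=True`` to gate both groups.
        """
        a = self.ratios(qc=qc, roi=True)
        b = other.ratios(qc=qc, roi=True) if isinstance(other, LactatePyruvateResults) else np.asarray(other, float)
        return compare_voxel_groups(a, b)

    def summary(self) -> str:
        vals_all = self.ratios(qc=False)
        vals_qc = self.ratios(qc=True)
        n_roi = int(self.map.roi_mask.sum())
        lines = [
            "Lactate/pyruvate MRSI fit",
            "-------------------------",
            f"grid                : {self.map.ratio.shape[0]}x{self.map.ratio.shape[1]}",
            f"voxels fitted       : {len(self.fits)}",
            f"voxels in ROI       : {n_roi}",
            f"QC-passing in ROI   : {len(vals_qc)} (SNR > {self.model.snr_threshold})",
            f"noise RMS           : {self.noise_rms:.4g}",
            f"mean ratio (all ROI): {np.mean(vals_all):.4f}" if len(vals_all) else "mean ratio (all ROI): n/a",
            f"mean ratio (QC)     : {np.mean(vals_qc):.4f}" if len(vals_qc) else "mean ratio (QC)     : n/a",
        ]
        return "\n".join(lines)

    def plot(self, proton_image: np.ndarray | None = None, ax=None):
        """Ratio map (QC-masked) overlaid on an optional proton image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n_rows, n_cols = self.map.ratio.shape
        fov = self.model.grid.fov_mm
        extent = (0, fov[0], fov[1], 0)
        if proton_image is not None:
            ax.imshow(proton_image, cmap="gray", extent=extent)
        im = ax.imshow(
            self.map.displayed, cmap="viridis", vmin=0, vmax=1,
            extent=extent, interpolation="nearest",
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        plt.colorbar(im, ax=ax, label="lactate / pyruvate")
        return ax
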