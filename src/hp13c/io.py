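"""Self-describing MRS container format and tabular/image exporters.

A container is a directory holding ``metadata.json`` (axis parameters,
timestamps, acquisition metadata, format version) plus the complex
time-domain samples, either as interleaved real/imaginary float64 binary
(``samples.bin``, bit-exact round trip) or as a portable CSV dialect
(``samples.csv`` with columns fid_index, index, re, im).

One reader serves all three payload kinds: a single FID, a 32x32 MRSI grid
(kind "mrsi") or a timestamped dynamic series (kind "dynamic").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mrsi import MRSIGrid, RatioMap
from .ph import DynamicSeries
from .spectral import FIDRecord, SpectralAxis, Spectrum

__all__ = [
    "SchemaError",
    "CorruptDataError",
    "write_container",
    "read_container",
    "spectrum_to_csv",
    "ratio_map_to_csv",
    "ratio_map_to_nifti",
    "image_to_nifti",
]

FORMAT_VERSION = "1"


class SchemaError(ValueError):
    """metadata.json is missing or malformed; the message names the field."""


class CorruptDataError(ValueError):
    """The sample payload does not match the metadata."""


def _axis_to_dict(axis: SpectralAxis) -> dict:
    return {
        "n_points": axis.n_points,
        "bandwidth_hz": axis.bandwidth_hz,
        "spectrometer_freq_mhz": axis.spectrometer_freq_mhz,
        "carrier_ppm": axis.carrier_ppm,
    }


def _require(meta: dict, field: str):
    cur = meta
    for part in field.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise SchemaError(f"metadata.json is missing required field '{field}'")
        cur = cur[part]
    return cur


def _axis_from_meta(meta: dict) -> SpectralAxis:
    return SpectralAxis(
        n_points=int(_require(meta, "axis.n_points")),
        bandwidth_hz=float(_require(meta, "axis.bandwidth_hz")),
        spectrometer_freq_mhz=float(_require(meta, "axis.spectrometer_freq_mhz")),
        carrier_ppm=float(_require(meta, "axis.carrier_ppm")),
    )


def _stack_samples(fids: list[FIDRecord]) -> np.ndarray:
    arr = np.stack([f.samples for f in fids])
    out = np.empty((arr.shape[0], arr.shape[1] * 2), dtype=np.float64)
    out[:, 0::2] = arr.real
    out[:, 1::2] = arr.imag
    return out


def write_container(path: str | Path, obj, fmt: str = "binary") -> Path:
    """Write a FIDRecord, MRSIGrid or DynamicSeries container directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"format_version": FORMAT_VERSION}

    if isinstance(obj, FIDRecord):
        meta["kind"] = "fid"
        meta["axis"] = _axis_to_dict(obj.axis)
        fids = [obj]
        if obj.timestamp_s is not None:
            meta["timestamps_s"] = [obj.timestamp_s]
        meta["flip_angle_deg"] = obj.flip_angle_deg
        meta["tr_s"] = obj.tr_s
    elif isinstance(obj, MRSIGrid):
        meta["kind"] = "mrsi"
        meta["axis"] = _axis_to_dict(obj.axis)
        meta["grid"] = {
            "shape": list(obj.shape),
            "fov_mm": list(obj.fov_mm),
            "slice_thickness_mm": obj.slice_thickness_mm,
            "origin_mm": list(obj.origin_mm),
        }
        fids = [obj.fids[r, c] for r in range(obj.shape[0]) for c in range(obj.shape[1])]
    elif isinstance(obj, DynamicSeries):
        meta["kind"] = "dynamic"
        meta["axis"] = _axis_to_dict(obj.axis)
        meta["timestamps_s"] = [float(t) for t in obj.timestamps_s]
        meta["flip_angle_deg"] = obj.fids[0].flip_angle_deg
        fids = obj.fids
    else:
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")

    meta["n_fids"] = len(fids)
    data = _stack_samples(fids)
    if fmt == "binary":
        meta["samples_file"] = "samples.bin"
        meta["samples_format"] = "float64-interleaved"
        data.tofile(path / "samples.bin")
    elif fmt == "csv":
        meta["samples_file"] = "samples.csv"
        meta["samples_format"] = "csv"
        n_points = fids[0].axis.n_points
        frame = pd.DataFrame(
            {
                "fid_index": np.repeat(np.arange(len(fids)), n_points),
                "index": np.tile(np.arange(n_points), len(fids)),
                "re": data[:, 0::2].ravel(),
                "im": data[:, 1::2].ravel(),
            }
        )
        frame.to_csv(path / "samples.csv", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown container format '{fmt}'")

    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    return path


def _load_samples(path: Path, meta: dict, axis: SpectralAxis) -> np.ndarray:
    n_fids = int(_require(meta, "n_fids"))
    samples_file = path / _require(meta, "samples_file")
    if not samples_file.exists():
        raise CorruptDataError(f"sample payload '{samples_file.name}' is missing")
    expected = n_fids * axis.n_points * 2
    if samples_file.suffix == ".bin":
        raw = np.fromfile(samples_file, dtype=np.float64)
        if raw.size != expected:
            raise CorruptDataError(
                f"'{samples_file.name}' holds {raw.size} float64 values, "
                f"expected {expected} (truncation at offset {raw.size * 8} bytes?)"
            )
    else:
        frame = pd.read_csv(samples_file, float_precision="round_trip")
        for col in ("re", "im"):
            if col not in frame.columns:
                raise SchemaError(f"samples.csv is missing required column '{col}'")
        if 2 * len(frame) != expected:
            raise CorruptDataError(
                f"'{samples_file.name}' holds {len(frame)} rows, expected {expected // 2}"
            )
        raw = np.empty(expected)
        raw[0::2] = frame["re"].to_numpy(float)
        raw[1::2] = frame["im"].to_numpy(float)
    raw = raw.reshape(n_fids, axis.n_points * 2)
    return raw[:, 0::2] + 1j * raw[:, 1::2]


def read_container(path: str | Path) -> FIDRecord | MRSIGrid | DynamicSeries:
    """Read a container directory back into its typed object.

    Invariants are re-verified on load; binary containers round-trip
    bit-exactly through :func:`write_container`.
    """
    path = Path(path)
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise SchemaError(f"no metadata.json found in {path}")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"metadata.json is not valid JSON: {exc}") from exc
    version = _require(meta, "format_version")
    if version != FORMAT_VERSION:
        raise SchemaError(f"unsupported format_version '{version}'")
    kind = _require(meta, "kind")
    axis = _axis_from_meta(meta)
    samples = _load_samples(path, meta, axis)

    if kind == "fid":
        ts = meta.get("timestamps_s") or [None]
        return FIDRecord(
            samples=samples[0],
            axis=axis,
            timestamp_s=ts[0],
            flip_angle_deg=meta.get("flip_angle_deg"),
            tr_s=meta.get("tr_s"),
        )
    if kind == "mrsi":
        shape = tuple(_require(meta, "grid.shape"))
        if samples.shape[0] != shape[0] * shape[1]:
            raise CorruptDataError(
                f"sample count {samples.shape[0]} does not match grid shape {shape}"
            )
        fids = np.empty(shape, dtype=object)
        for i in range(samples.shape[0]):
            fids[i // shape[1], i % shape[1]] = FIDRecord(samples=samples[i], axis=axis)
        return MRSIGrid(
            fids=fids,
            axis=axis,
            fov_mm=tuple(_require(meta, "grid.fov_mm")),
            slice_thickness_mm=float(_require(meta, "grid.slice_thickness_mm")),
            origin_mm=tuple(meta["grid"].get("origin_mm", (0.0, 0.0))),
        )
    if kind == "dynamic":
        ts = _require(meta, "timestamps_s")
        if len(ts) != samples.shape[0]:
            raise CorruptDataError("timestamps_s length does not match sample count")
        fids = [
            FIDRecord(
                samples=samples[i], axis=axis, timestamp_s=float(ts[i]),
                flip_angle_deg=meta.get("flip_angle_deg"),
            )
            for i in range(samples.shape[0])
        ]
        return DynamicSeries(fids=fids)
    raise SchemaError(f"unknown container kind '{kind}'")


def spectrum_to_csv(spec: Spectrum, path: str | Path) -> Path:
    """Export a spectrum as (ppm, re, im) CSV for plotting."""
    path = Path(path)
    pd.DataFrame(
        {"ppm": spec.axis.ppm, "re": spec.values.real, "im": spec.values.imag}
    ).to_csv(path, index=False)
    return path


def ratio_map_to_csv(rmap: RatioMap, path: str | Path) -> Path:
    path = Path(path)
    rmap.to_frame().to_csv(path, index=False)
    return path


def ratio_map_to_nifti(rmap: RatioMap, fov_mm: tuple[float, float], path: str | Path) -> Path:
    """Ratio, QC and ROI planes as a 3-volume NIfTI aligned to the FOV."""
    import nibabel as nib

    n_rows, n_cols = rmap.ratio.shape
    vox = (fov_mm[0] / n_cols, fov_mm[1] / n_rows)
    affine = np.diag([vox[0], vox[1], 1.0, 1.0])
    stack = np.stack(
        [rmap.ratio, rmap.qc_mask.astype(float), rmap.roi_mask.astype(float)], axis=-1
    )[:, :, None, :]
    img = nib.Nifti1Image(np.ascontiguousarray(stack.transpose(1, 0, 2, 3)), affine)
    path = Path(path)
    nib.save(img, path)
    return path


def image_to_nifti(image: np.ndarray, fov_mm: tuple[float, float], path: str | Path) -> Path:
    """2D image (e.g. the proton reference) as NIfTI with mm pixel spacing."""
    import nibabel as nib

    n_rows, n_cols = image.shape
    affine = np.diag([fov_mm[0] / n_cols, fov_mm[1] / n_rows, 1.0, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(image.T[:, :, None]), affine)
    path = Path(path)
    nib.save(img, path)
    return path
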