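"""Readers and writers for the on-disk formats.

Stacks and derived maps travel as TIFF (raw: 16-bit grayscale multi-page;
derived: 32-bit float with NaN marking invalid pixels) with acquisition
metadata in a sidecar JSON. Masks are 8-bit PNG (nonzero = in ROI). Decays,
timecourses, control points and extinction overrides are CSV; calibration,
affine maps, schedules, configs and run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError
from .lifetime import DecayTrace, SternVolmerCalibration
from .patterning import AffineMap2D, PatternSchedule, ROISet
from .speckle import SpeckleStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "read_roiset",
    "write_roiset",
    "read_decay",
    "write_decay",
    "read_timecourse",
    "write_timecourse",
    "read_calibration",
    "write_calibration",
    "read_affine",
    "write_affine",
    "read_schedule",
    "write_schedule",
    "read_control_points",
    "write_control_points",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: SpeckleStack) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if frames.max() > np.iinfo(np.uint16).max:
        raise FormatError("intensities exceed the 16-bit range")
    tifffile.imwrite(path, np.round(frames).astype(np.uint16))
    _sidecar_path(path).write_text(
        json.dumps(
            {"exposure_s": stack.exposure_T, "frame_rate_hz": stack.frame_rate},
            indent=2,
        )
    )


def read_stack(
    path: str | Path,
    exposure_T: float | None = None,
    frame_rate: float | None = None,
) -> SpeckleStack:
    """Read a multi-page grayscale TIFF stack.

    Metadata comes from the sidecar JSON next to the file; explicit
    arguments override it. Missing exposure is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such stack: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {frames.shape} "
            "(RGB input is not supported)"
        )
    if frames.shape[0] == 0:
        raise FormatError(f"{path}: stack contains zero frames")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    exposure = exposure_T if exposure_T is not None else meta.get("exposure_s")
    rate = frame_rate if frame_rate is not None else meta.get("frame_rate_hz", 60.0)
    if exposure is None:
        raise FormatError(
            f"{path}: no exposure time in sidecar {sidecar.name} and none supplied"
        )
    return SpeckleStack(frames=frames.astype(np.float64), exposure_T=float(exposure),
                        frame_rate=float(rate))


def write_map(path: str | Path, data: np.ndarray, valid_mask: np.ndarray | None = None) -> None:
    """Write a derived map as 32-bit float TIFF; invalid pixels become NaN."""
    arr = np.asarray(data, dtype=np.float32).copy()
    if valid_mask is not None:
        arr[~np.asarray(valid_mask, dtype=bool)] = np.nan
    tifffile.imwrite(Path(path), arr)


def read_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-page 2-D map")
    return arr.astype(np.float64)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse identical channels rather than reject
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_roiset(directory: str | Path, rois: ROISet) -> None:
    """Write each mask as PNG plus an index JSON with the pixel scale."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in rois.masks.items():
        write_mask(directory / f"{name}.png", mask)
    (directory / "roiset.json").write_text(
        json.dumps(
            {"pixel_scale_mm": rois.pixel_scale, "rois": sorted(rois.masks)}, indent=2
        )
    )


def read_roiset(directory: str | Path) -> ROISet:
    directory = Path(directory)
    index = directory / "roiset.json"
    if not index.exists():
        raise FormatError(f"{directory}: missing roiset.json index")
    meta = json.loads(index.read_text())
    masks = {name: read_mask(directory / f"{name}.png") for name in meta["rois"]}
    return ROISet(masks=masks, pixel_scale=float(meta["pixel_scale_mm"]))


def write_decay(path: str | Path, trace: DecayTrace) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.t, "signal": trace.signal}).to_csv(path, index=False)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "n_averaged": trace.n_averaged,
                "sample_rate_hz": trace.sample_rate,
                "offset_applied": trace.offset_applied,
            },
            indent=2,
        )
    )


def read_decay(path: str | Path) -> DecayTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "signal"}.issubset(df.columns):
        raise FormatError(f"{path}: decay CSV must have columns time_s, signal")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return DecayTrace(
        t=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        n_averaged=int(meta.get("n_averaged", 1)),
        sample_rate=meta.get("sample_rate_hz"),
        offset_applied=bool(meta.get("offset_applied", False)),
    )


def write_timecourse(path: str | Path, rows: pd.DataFrame | Iterable[Mapping]) -> None:
    """Write a timecourse CSV; floats use shortest-roundtrip formatting."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(Path(path), index=False)


def read_timecourse(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap as a format error
        raise FormatError(f"{path}: unreadable timecourse CSV ({exc})") from exc
    if df.columns.size == 0 or any(c.startswith("Unnamed") for c in df.columns):
        raise FormatError(f"{path}: malformed timecourse header")

    def _numeric(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    if all(_numeric(c) for c in df.columns):
        raise FormatError(f"{path}: header row looks like data, not column names")
    return df


def write_calibration(path: str | Path, cal: SternVolmerCalibration) -> None:
    payload = {
        "kq_per_mmhg_s": cal.kq,
        "tau0_s": cal.tau0,
        "sv_regime_tau_s": cal.sv_regime_tau,
    }
    if cal.table is not None:
        payload["table"] = np.asarray(cal.table).tolist()
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration(path: str | Path) -> SternVolmerCalibration:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: unreadable calibration JSON ({exc})") from exc
    try:
        return SternVolmerCalibration(
            kq=float(payload["kq_per_mmhg_s"]),
            tau0=float(payload["tau0_s"]),
            sv_regime_tau=float(payload.get("sv_regime_tau_s", 16e-6)),
            table=np.asarray(payload["table"], dtype=float) if "table" in payload else None,
        )
    except KeyError as exc:
        raise FormatError(f"{path}: calibration JSON missing key {exc}") from exc


def write_affine(path: str | Path, amap: AffineMap2D) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "coefficients": amap.coefficients.tolist(),
                "rms_residual": amap.rms_residual,
            },
            indent=2,
        )
    )


def read_affine(path: str | Path) -> AffineMap2D:
    payload = json.loads(Path(path).read_text())
    return AffineMap2D(
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        rms_residual=float(payload.get("rms_residual", 0.0)),
    )


def write_schedule(path: str | Path, schedule: PatternSchedule) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "pattern_rate_hz": schedule.pattern_rate,
                "decays_per_pattern": schedule.decays_per_pattern,
                "pulse_width_s": schedule.pulse_width,
                "rep_rate_hz": schedule.rep_rate,
                "n_patterns": schedule.n_patterns,
            },
            indent=2,
        )
    )


def read_schedule(path: str | Path) -> PatternSchedule:
    payload = json.loads(Path(path).read_text())
    return PatternSchedule(
        pattern_rate=float(payload["pattern_rate_hz"]),
        decays_per_pattern=int(payload["decays_per_pattern"]),
        pulse_width=float(payload["pulse_width_s"]),
        rep_rate=float(payload["rep_rate_hz"]),
        n_patterns=int(payload["n_patterns"]),
    )


def write_control_points(path: str | Path, pairs: Iterable[tuple]) -> None:
    rows = [
        {"x_cam": c[0], "y_cam": c[1], "x_dmd": d[0], "y_dmd": d[1]} for c, d in pairs
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_control_points(path: str | Path) -> list[tuple]:
    df = pd.read_csv(Path(path))
    required = {"x_cam", "y_cam", "x_dmd", "y_dmd"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: control points need columns {sorted(required)}")
    return [
        ((r.x_cam, r.y_cam), (r.x_dmd, r.y_dmd)) for r in df.itertuples(index=False)
    ]
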