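"""Camera <-> DMD targeting geometry and acquisition scheduling.

Conventions: 0-based pixel indices, points are (x, y) = (column, row) at
pixel centers, tile intervals are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleScheduleError, ParameterError

__all__ = [
    "AffineMap2D",
    "ROISet",
    "TileGrid",
    "PatternSchedule",
    "DMD_SHAPE",
    "estimate_affine",
    "mask_to_dmd",
    "make_tile_grid",
    "duty_cycle",
    "acquisition_plan",
    "pixel_scale_from_fov",
]

# (rows, cols) of the DLP3000 mirror array
DMD_SHAPE = (608, 684)
DMD_MIRROR_PITCH_UM = 7.6  # metadata only; magnification lives in the affine map


@dataclass
class AffineMap2D:
    """2-D affine map camera (x, y) -> DMD (x, y), as a 2x3 matrix."""

    coefficients: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (2, 3):
            raise ParameterError("affine coefficients must be a 2x3 matrix")
        if abs(np.linalg.det(self.coefficients[:, :2])) < 1e-12:
            raise ParameterError("affine map is degenerate (singular linear part)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points of (x, y) through the affine transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.coefficients[:, :2].T + self.coefficients[:, 2]

    def inverse(self) -> "AffineMap2D":
        L = self.coefficients[:, :2]
        t = self.coefficients[:, 2]
        Linv = np.linalg.inv(L)
        return AffineMap2D(np.column_stack([Linv, -Linv @ t]))


@dataclass
class ROISet:
    """Named boolean masks in camera coordinates with a physical pixel scale."""

    masks: dict[str, np.ndarray]
    pixel_scale: float  # mm per pixel

    def __post_init__(self) -> None:
        if not self.pixel_scale > 0:
            raise ParameterError("pixel_scale must be positive")
        clean: dict[str, np.ndarray] = {}
        for name, mask in self.masks.items():
            arr = np.asarray(mask, dtype=bool)
            if arr.ndim != 2:
                raise ParameterError(f"ROI {name!r} mask must be 2-D")
            clean[name] = arr
        self.masks = clean

    @property
    def areas(self) -> dict[str, float]:
        """Per-ROI area in mm^2 (pixel count times pixel_scale^2)."""
        return {
            name: float(np.count_nonzero(mask)) * self.pixel_scale**2
            for name, mask in self.masks.items()
        }


@dataclass
class TileGrid:
    """A rectangular grid of tiles over a physical extent."""

    origin: tuple[float, float]  # (x, y) camera pixels of the grid corner
    extent: tuple[float, float]  # (width, height) in mm
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ParameterError("tile counts must be positive")
        if not (self.extent[0] > 0 and self.extent[1] > 0):
            raise ParameterError("grid extent must be positive")

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def tile_area_mm2(self) -> float:
        """Nominal per-tile area: width * height / (n_cols * n_rows)."""
        return self.extent[0] * self.extent[1] / self.n_tiles


@dataclass
class PatternSchedule:
    """Timing of a sequential pattern projection with gated excitation."""

    pattern_rate: float  # Hz
    decays_per_pattern: int
    pulse_width: float  # s
    rep_rate: float  # Hz
    n_patterns: int

    def __post_init__(self) -> None:
        if min(self.pattern_rate, self.pulse_width, self.rep_rate) <= 0:
            raise ParameterError("pattern_rate, pulse_width and rep_rate must be positive")
        if self.decays_per_pattern < 1 or self.n_patterns < 1:
            raise ParameterError("decays_per_pattern and n_patterns must be >= 1")
        duty_cycle(self.pulse_width, self.rep_rate)  # validates duty < 1


def estimate_affine(pairs: Sequence[tuple]) -> AffineMap2D:
    """Least-squares affine map from >= 3 (camera point, dmd point) pairs.

    Exact (machine-precision residual) for 3 noncollinear pairs; for more,
    the RMS residual is recorded on the returned map.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ParameterError(f"need >= 3 point pairs, got {len(pairs)}")
    cam = np.asarray([p[0] for p in pairs], dtype=np.float64)
    dmd = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if cam.shape[1] != 2 or dmd.shape[1] != 2:
        raise ParameterError("points must be 2-D (x, y)")
    design = np.column_stack([cam, np.ones(len(pairs))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 3:
        raise ParameterError("camera points are collinear; affine map underdetermined")
    sol, *_ = np.linalg.lstsq(design, dmd, rcond=None)
    coeffs = sol.T  # rows: x', y'; cols: a, b, t
    resid = design @ sol - dmd
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineMap2D(coefficients=coeffs, rms_residual=rms)


def mask_to_dmd(
    mask: np.ndarray,
    amap: AffineMap2D,
    dmd_shape: tuple[int, int] = DMD_SHAPE,
) -> tuple[np.ndarray, float]:
    """Rasterize a camera-space binary mask into DMD coordinates.

    Each DMD pixel center is pulled back through the inverse map and takes
    the nearest camera pixel's value (false outside the camera frame).
    Returns the DMD mask and the clipped fraction: the share of the mask's
    true camera pixels whose forward image falls outside the DMD frame.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ParameterError("mask must be 2-D")
    inv = amap.inverse()
    rows, cols = dmd_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    cam = inv.apply(pts)
    ci = np.rint(cam[:, 0]).astype(np.int64)  # camera column
    ri = np.rint(cam[:, 1]).astype(np.int64)  # camera row
    inside = (ri >= 0) & (ri < mask.shape[0]) & (ci >= 0) & (ci < mask.shape[1])
    out = np.zeros(rows * cols, dtype=bool)
    out[inside] = mask[ri[inside], ci[inside]]

    n_true = np.count_nonzero(mask)
    if n_true:
        src_r, src_c = np.nonzero(mask)
        fwd = amap.apply(np.column_stack([src_c, src_r]).astype(np.float64))
        fc = np.rint(fwd[:, 0]).astype(np.int64)
        fr = np.rint(fwd[:, 1]).astype(np.int64)
        on_dmd = (fr >= 0) & (fr < rows) & (fc >= 0) & (fc < cols)
        clipped = 1.0 - np.count_nonzero(on_dmd) / n_true
    else:
        clipped = 0.0
    if clipped > 0:
        warnings.warn(f"{clipped:.1%} of the mask maps outside the DMD frame")
    return out.reshape(rows, cols), clipped


def make_tile_grid(
    grid: TileGrid,
    pixel_scale: float,
    frame_shape: tuple[int, int] | None = None,
) -> ROISet:
    """Rasterize a tile grid into a named set of disjoint rectangular masks.

    Tiles are half-open in both axes, partitioning every camera pixel whose
    center lies in [x0, x0 + W) x [y0, y0 + H). Tile names are
    ``tile_{row:02d}_{col:02d}``, row-major from the grid origin.
    """
    if not pixel_scale > 0:
        raise ParameterError("pixel_scale must be positive")
    x0, y0 = grid.origin
    w_px = grid.extent[0] / pixel_scale
    h_px = grid.extent[1] / pixel_scale
    if frame_shape is None:
        frame_shape = (int(np.ceil(y0 + h_px)), int(np.ceil(x0 + w_px)))
    rows, cols = frame_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    in_x = (xx >= x0) & (xx < x0 + w_px)
    in_y = (yy >= y0) & (yy < y0 + h_px)
    inside = in_x & in_y
    # half-open tile index; floor keeps the partition exact
    jj = np.floor((xx - x0) * grid.n_cols / w_px).astype(np.int64)
    ii = np.floor((yy - y0) * grid.n_rows / h_px).astype(np.int64)
    masks: dict[str, np.ndarray] = {}
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            masks[f"tile_{r:02d}_{c:02d}"] = inside & (ii == r) & (jj == c)
    return ROISet(masks=masks, pixel_scale=pixel_scale)


def duty_cycle(pulse_width: float, rep_rate: float) -> float:
    """Fraction of time the excitation is on: pulse_width * rep_rate."""
    if pulse_width < 0 or rep_rate <= 0:
        raise ParameterError("pulse_width must be >= 0 and rep_rate > 0")
    duty = pulse_width * rep_rate
    if duty >= 1.0:
        raise InfeasibleScheduleError(
            f"duty cycle {duty:.3g} >= 1: pulses longer than the repetition period"
        )
    return duty


def acquisition_plan(schedule: PatternSchedule) -> dict:
    """Timing summary of a pattern sequence.

    total_time = n_patterns / pattern_rate;
    per_pattern_decay_time = decays_per_pattern / rep_rate;
    feasible iff the decays fit within one pattern slot.
    """
    total_time = schedule.n_patterns / schedule.pattern_rate
    per_pattern_decay_time = schedule.decays_per_pattern / schedule.rep_rate
    return {
        "total_time": total_time,
        "per_pattern_decay_time": per_pattern_decay_time,
        "feasible": bool(per_pattern_decay_time <= 1.0 / schedule.pattern_rate),
    }


def pixel_scale_from_fov(
    fov: tuple[float, float], sensor: tuple[int, int], tol: float = 0.02
) -> float:
    """Physical pixel scale (mm/pixel) from field of view and sensor size.

    ``fov`` is (width mm, height mm), ``sensor`` is (cols, rows). The two
    per-axis scales must agree within ``tol`` (default 2%); their mean is
    returned.
    """
    (w, h), (cols, rows) = fov, sensor
    if min(w, h) <= 0 or min(cols, rows) <= 0:
        raise ParameterError("field of view and sensor dimensions must be positive")
    sx, sy = w / cols, h / rows
    if abs(sx - sy) / min(sx, sy) > tol:
        raise ParameterError(
            f"anisotropic pixels: x scale {sx:.6g} vs y scale {sy:.6g} mm/px"
        )
    return 0.5 * (sx + sy)
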