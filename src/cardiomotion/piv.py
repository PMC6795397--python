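"""Windowed cross-correlation PIV for time-lapse monolayer recordings.

Displacement of each interrogation window is the argmax of the normalized
cross-correlation (NCC) between the reference-frame window and a search
region in the target frame, refined to subpixel precision by a three-point
Gaussian (default) or parabolic peak fit.  The diastolic reference frame is
chosen as the frame with minimal consecutive-frame cell velocity.

Conventions: pixel coordinates with the origin at the image top-left, x
rightward, y downward; ``u``/``v`` are the x/y displacement components in
px of material imaged at a window in the reference frame.  Window centers
sit at half-open window midpoints (top-left position + window_size / 2).
Border windows lacking the full search margin are marked invalid rather
than zero-padded, as are flat (zero-variance) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.feature import match_template

__all__ = [
    "FrameStack",
    "PivParams",
    "DisplacementField",
    "piv_displacement",
    "consecutive_speed_trace",
    "select_reference_frame",
    "displacement_series",
]


@dataclass
class FrameStack:
    """Ordered grayscale frames with a known frame rate.

    ``frames`` is an (n, h, w) float array; ``pixel_size`` (µm/px) is
    optional and unused by the nondimensional divergence pipeline.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("FrameStack needs >= 2 frames of identical shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @classmethod
    def from_tiff(cls, path: str | Path, frame_rate: float, pixel_size: float | None = None):
        """Read a multi-page TIFF; integer data are rescaled to [0, 1]."""
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(float)
        return cls(frames=arr, frame_rate=frame_rate, pixel_size=pixel_size)

    def to_tiff(self, path: str | Path, dtype: str = "uint16") -> None:
        """Write as multi-page grayscale TIFF (8- or 16-bit)."""
        if dtype not in ("uint8", "uint16"):
            raise ValueError("dtype must be 'uint8' or 'uint16'")
        info = np.iinfo(dtype)
        data = np.clip(self.frames, 0.0, 1.0)
        tifffile.imwrite(str(path), (data * info.max).round().astype(dtype))


@dataclass(frozen=True)
class PivParams:
    """Interrogation parameters for windowed cross-correlation.

    ``search_margin`` extends the searched region ``margin`` px beyond the
    window on every side, bounding the detectable displacement.
    ``validation_threshold`` (px) flags vectors deviating from their 3×3
    neighborhood median by more than the threshold and replaces them by that
    median; ``None`` disables validation.
    """

    window_size: int = 32
    overlap: int = 16
    search_margin: int = 8
    subpixel: str = "gaussian3"  # "gaussian3" | "parabolic" | "none"
    validation_threshold: float | None = 2.0

    def __post_init__(self) -> None:
        if self.window_size < 8:
            raise ValueError("window_size must be >= 8")
        if not 0 <= self.overlap < self.window_size:
            raise ValueError("overlap must satisfy 0 <= overlap < window_size")
        if self.search_margin < 0:
            raise ValueError("search_margin must be nonnegative")
        if self.subpixel not in ("gaussian3", "parabolic", "none"):
            raise ValueError("subpixel must be gaussian3, parabolic, or none")
        if self.validation_threshold is not None and self.validation_threshold <= 0:
            raise ValueError("validation_threshold must be positive")

    @property
    def step(self) -> int:
        return self.window_size - self.overlap


@dataclass
class DisplacementField:
    """Displacement vectors on a regular window grid at one time point.

    ``grid_x``/``grid_y`` are the 1-D window-center coordinates (px);
    ``u``/``v`` are (ny, nx) displacement components (px) relative to the
    reference frame, NaN where ``valid`` is False.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    t: float = 0.0

    @property
    def spacing(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0]) if self.grid_x.size > 1 else float("nan")

    def mean_speed(self) -> float:
        """Spatial mean of |(u, v)| over valid windows."""
        if not self.valid.any():
            raise ValueError("no valid windows")
        return float(np.mean(np.hypot(self.u[self.valid], self.v[self.valid])))

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "t": self.t,
                "grid_x": X.ravel(),
                "grid_y": Y.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _window_grid(shape: tuple[int, int], params: PivParams):
    """Top-left window positions (xs, ys) covering the image."""
    h, w = shape
    ws = params.window_size
    xs = np.arange(0, w - ws + 1, params.step)
    ys = np.arange(0, h - ws + 1, params.step)
    if xs.size == 0 or ys.size == 0:
        raise ValueError(f"image {shape} smaller than one {ws}px window")
    return xs, ys


def _subpixel_offset(cm1: float, c0: float, cp1: float, mode: str) -> float:
    """Peak offset in [-0.5, 0.5] from three correlation samples."""
    if mode == "none":
        return 0.0
    if mode == "gaussian3" and min(cm1, c0, cp1) > 0:
        lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
        denom = lm1 - 2 * l0 + lp1
        if denom < 0:
            return float(np.clip(0.5 * (lm1 - lp1) / denom, -0.5, 0.5))
    denom = cm1 - 2 * c0 + cp1
    if denom < 0:  # parabolic fallback; requires a strict local max
        return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))
    return 0.0


def _median_validate(u: np.ndarray, v: np.ndarray, valid: np.ndarray, threshold: float):
    """Replace vectors far from their 3x3 neighborhood median by that median."""
    ny, nx = u.shape
    med_u = np.full_like(u, np.nan)
    med_v = np.full_like(v, np.nan)
    for i in range(ny):
        for j in range(nx):
            if not valid[i, j]:
                continue
            i0, i1 = max(i - 1, 0), min(i + 2, ny)
            j0, j1 = max(j - 1, 0), min(j + 2, nx)
            mask = valid[i0:i1, j0:j1].copy()
            mask[i - i0, j - j0] = False  # exclude self
            if not mask.any():
                continue
            med_u[i, j] = np.median(u[i0:i1, j0:j1][mask])
            med_v[i, j] = np.median(v[i0:i1, j0:j1][mask])
    resid = np.hypot(u - med_u, v - med_v)
    outlier = valid & np.isfinite(resid) & (resid > threshold)
    u = u.copy()
    v = v.copy()
    u[outlier] = med_u[outlier]
    v[outlier] = med_v[outlier]
    return u, v


def piv_displacement(reference: np.ndarray, frame: np.ndarray, params: PivParams | None = None,
                     t: float = 0.0) -> DisplacementField:
    """Estimate the displacement field mapping the reference to the frame.

    Per window, displacement is the NCC argmax between the reference window
    and the search region in the frame, subpixel-refined.  Flat windows and
    border windows without the full search margin are marked invalid.
    """
    params = params or PivParams()
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if reference.shape != frame.shape:
        raise ValueError("reference and frame must have the same shape")
    ws, m = params.window_size, params.search_margin
    h, w = reference.shape
    if h < ws + 2 * m or w < ws + 2 * m:
        raise ValueError(
            f"image {reference.shape} smaller than window_size + 2*search_margin = {ws + 2 * m}"
        )
    xs, ys = _window_grid(reference.shape, params)
    ny, nx = ys.size, xs.size
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            if y0 < m or x0 < m or y0 + ws + m > h or x0 + ws + m > w:
                continue  # border: search margin unavailable
            win = reference[y0 : y0 + ws, x0 : x0 + ws]
            if win.std() == 0:
                continue  # flat window: correlation undefined
            search = frame[y0 - m : y0 + ws + m, x0 - m : x0 + ws + m]
            cc = match_template(search, win)
            if not np.isfinite(cc).all():
                continue
            py, px = np.unravel_index(np.argmax(cc), cc.shape)
            dy, dx = float(py - m), float(px - m)
            if 0 < py < cc.shape[0] - 1:
                dy += _subpixel_offset(cc[py - 1, px], cc[py, px], cc[py + 1, px], params.subpixel)
            if 0 < px < cc.shape[1] - 1:
                dx += _subpixel_offset(cc[py, px - 1], cc[py, px], cc[py, px + 1], params.subpixel)
            u[i, j], v[i, j] = dx, dy
            valid[i, j] = True
    if params.validation_threshold is not None and valid.any():
        u, v = _median_validate(u, v, valid, params.validation_threshold)
    centers_x = xs + ws / 2.0
    centers_y = ys + ws / 2.0
    return DisplacementField(grid_x=centers_x, grid_y=centers_y, u=u, v=v, valid=valid, t=t)


def consecutive_speed_trace(stack: FrameStack, params: PivParams | None = None) -> np.ndarray:
    """Mean cell speed (px/frame) between each pair of consecutive frames."""
    params = params or PivParams()
    speeds = np.empty(stack.n_frames - 1)
    for k in range(stack.n_frames - 1):
        fld = piv_displacement(stack.frames[k], stack.frames[k + 1], params)
        if not fld.valid.any():
            raise ValueError(f"no valid PIV windows between frames {k} and {k + 1}")
        speeds[k] = fld.mean_speed()
    return speeds


def select_reference_frame(stack: FrameStack, params: PivParams | None = None) -> int:
    """Index of the most quiescent (diastolic) frame.

    Each frame is scored by the mean of its speeds to the previous and next
    frame (one-sided at the ends); the minimum wins, ties going to the
    smallest index.
    """
    s = consecutive_speed_trace(stack, params)
    score = np.empty(stack.n_frames)
    score[0] = s[0]
    score[-1] = s[-1]
    if stack.n_frames > 2:
        score[1:-1] = 0.5 * (s[:-1] + s[1:])
    return int(np.argmin(score))


def displacement_series(
    stack: FrameStack, ref_index: int, params: PivParams | None = None
) -> list[DisplacementField]:
    """One displacement field per frame, all relative to a fixed reference.

    The field at ``ref_index`` is identically zero by construction (a frame
    correlated against itself), keeping D(t) exactly zero at the reference.
    """
    params = params or PivParams()
    if not 0 <= ref_index < stack.n_frames:
        raise ValueError(f"ref_index {ref_index} outside [0, {stack.n_frames})")
    reference = stack.frames[ref_index]
    times = stack.times
    fields = []
    for k in range(stack.n_frames):
        if k == ref_index:
            template = piv_displacement(reference, reference, params, t=times[k])
            template.u[template.valid] = 0.0
            template.v[template.valid] = 0.0
            fields.append(template)
        else:
            fields.append(piv_displacement(reference, stack.frames[k], params, t=times[k]))
    return fields


def fields_to_csv(fields: list[DisplacementField], path: str | Path) -> None:
    """Write a displacement-field series as long-format CSV."""
    pd.concat([f.to_frame() for f in fields], ignore_index=True).to_csv(path, index=False)
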