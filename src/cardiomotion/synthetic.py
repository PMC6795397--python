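"""Synthetic beating-monolayer videos with analytically known motion.

A static speckle texture (Gaussian blobs, emulating wheat-germ-agglutinin
membrane speckles under phase contrast) is warped frame by frame with a
prescribed periodic contraction displacement field.  Because the field is
analytic, the divergence — and hence the contractility trace D(t) and every
beat metric derived from it — is known in closed form, giving the full
pipeline an exact ground truth without any recorded data.

Two motion models are provided:

``affine_contraction``
    u*(x, t) = -s(t) (x - c).  The divergence is spatially uniform,
    div u* = -2 s(t) = -a(t), so the amplitude waveform a(t) *is* the
    ground-truth |divergence| trace.

``radial_gaussian``
    u*(x, t) = -s(t) (x - c) exp(-r² / 2σ²), a localized contraction focus
    with closed-form divergence -s(t) exp(-r²/2σ²) (2 - r²/σ²).

Amplitude waveforms start each cycle with a rest (diastolic) segment of
duration ``rest_fraction * period`` followed by a pulse occupying the
remainder, so a(0) = 0 and recordings start at rest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import map_coordinates

from .qpcr import CqTable

__all__ = [
    "MotionSpec",
    "GroundTruth",
    "make_speckle_texture",
    "analytic_displacement",
    "analytic_divergence",
    "ground_truth_trace",
    "ground_truth",
    "render_beating_video",
    "simulate_cq_table",
]

_KINDS = ("affine_contraction", "radial_gaussian")
_WAVEFORMS = ("sin2_pulse", "triangle", "custom")


@dataclass(frozen=True)
class MotionSpec:
    """Prescribed periodic contraction of a monolayer field of view.

    Parameters
    ----------
    kind:
        ``affine_contraction`` (uniform divergence) or ``radial_gaussian``
        (localized contraction focus of width ``sigma``).
    center:
        Contraction center ``(x, y)`` in pixels.
    period:
        Beat period in seconds.
    peak_divergence:
        Peak of the ground-truth |divergence| trace (nondimensional).
    rest_fraction:
        Fraction of each cycle spent at rest (zero amplitude) before the
        contraction pulse.
    frame_rate:
        Acquisition rate in Hz.
    n_frames:
        Number of frames in the recording.
    width, height:
        Frame dimensions in pixels.
    waveform:
        ``sin2_pulse`` (default), ``triangle``, or ``custom`` with
        ``custom_samples`` giving amplitudes at equally spaced phases of one
        full period (linearly interpolated, wrapping).
    sigma:
        Gaussian width (px) of the radial motion model; unused for affine.
    """

    kind: str = "affine_contraction"
    center: tuple[float, float] = (128.0, 128.0)
    period: float = 1.1
    peak_divergence: float = 0.02
    rest_fraction: float = 0.7
    frame_rate: float = 20.0
    n_frames: int = 200
    width: int = 256
    height: int = 256
    waveform: str = "sin2_pulse"
    custom_samples: tuple[float, ...] | None = None
    sigma: float = 80.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.peak_divergence < 0:
            raise ValueError("peak_divergence must be nonnegative")
        if not 0 <= self.rest_fraction < 1:
            raise ValueError("rest_fraction must lie in [0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.width < 1 or self.height < 1:
            raise ValueError("frame dimensions must be positive")
        if self.waveform == "custom":
            if not self.custom_samples:
                raise ValueError("custom waveform requires custom_samples")
            if abs(self.custom_samples[0]) > 0:
                raise ValueError("amplitude at phase 0 must be zero (diastolic rest)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def amplitude(self, t):
        """Ground-truth |divergence| waveform a(t); a(0) = 0.

        Each cycle is a rest segment of length ``rest_fraction * period``
        followed by a pulse over the remaining ``(1 - rest_fraction)`` of the
        period, peaking at ``peak_divergence``.
        """
        t = np.asarray(t, dtype=float)
        phase = np.mod(t / self.period, 1.0)
        if self.waveform == "custom":
            samples = np.asarray(self.custom_samples, dtype=float)
            grid = np.linspace(0.0, 1.0, samples.size + 1)
            return np.interp(phase, grid, np.append(samples, samples[0]))
        x = (phase - self.rest_fraction) / (1.0 - self.rest_fraction)
        active = phase >= self.rest_fraction
        if self.waveform == "sin2_pulse":
            pulse = np.sin(np.pi * x) ** 2
        else:  # triangle
            pulse = 1.0 - np.abs(2.0 * x - 1.0)
        return np.where(active, self.peak_divergence * pulse, 0.0)

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["center"] = list(self.center)
        if self.custom_samples is not None:
            data["custom_samples"] = list(self.custom_samples)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotionSpec":
        data = yaml.safe_load(Path(path).read_text())
        data["center"] = tuple(data["center"])
        if data.get("custom_samples") is not None:
            data["custom_samples"] = tuple(data["custom_samples"])
        return cls(**data)


def make_speckle_texture(
    width: int,
    height: int,
    n_speckles: int = 2000,
    speckle_sigma: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Render a static Gaussian-blob speckle image with intensities in [0, 1].

    Blob centers are uniform over the frame; each blob is an isotropic
    Gaussian of width ``speckle_sigma`` px with a random (0.3–1.0) peak
    weight, summed and rescaled to span [0, 1].  Deterministic per seed.
    """
    if width < 64 or height < 64:
        raise ValueError("texture must be at least 64x64 px")
    if n_speckles < 1:
        raise ValueError("need at least one speckle")
    if speckle_sigma <= 0:
        raise ValueError("speckle_sigma must be positive")
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width), dtype=float)
    cx = rng.uniform(0, width, n_speckles)
    cy = rng.uniform(0, height, n_speckles)
    amp = rng.uniform(0.3, 1.0, n_speckles)
    # render each blob on a local patch only; 4 sigma covers >99.99% of mass
    r = max(1, int(np.ceil(4 * speckle_sigma)))
    for x0, y0, a in zip(cx, cy, amp):
        xi0, xi1 = int(np.floor(x0 - r)), int(np.ceil(x0 + r)) + 1
        yi0, yi1 = int(np.floor(y0 - r)), int(np.ceil(y0 + r)) + 1
        xi0, yi0 = max(xi0, 0), max(yi0, 0)
        xi1, yi1 = min(xi1, width), min(yi1, height)
        if xi0 >= xi1 or yi0 >= yi1:
            continue
        xs = np.arange(xi0, xi1)
        ys = np.arange(yi0, yi1)
        gx = np.exp(-((xs - x0) ** 2) / (2 * speckle_sigma**2))
        gy = np.exp(-((ys - y0) ** 2) / (2 * speckle_sigma**2))
        img[yi0:yi1, xi0:xi1] += a * np.outer(gy, gx)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img


def _scale(spec: MotionSpec, t) -> np.ndarray:
    """Linear contraction scale s(t) = a(t) / 2 (so that div u* = -a(t))."""
    return np.asarray(spec.amplitude(t), dtype=float) / 2.0


def analytic_displacement(
    spec: MotionSpec, points: np.ndarray, t: float, *, check_bounds: bool = True
) -> np.ndarray:
    """Ground-truth displacement u*(x, t) in px at the given points.

    ``points`` is an (N, 2) array of (x, y) pixel coordinates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 2:
        raise ValueError("points must be (N, 2) of (x, y)")
    if check_bounds:
        if not (0 <= t <= spec.duration):
            raise ValueError(f"time {t} outside the recording [0, {spec.duration}]")
        x, y = points[:, 0], points[:, 1]
        if (x < 0).any() or (x > spec.width).any() or (y < 0).any() or (y > spec.height).any():
            raise ValueError("point outside the frame")
    s = float(_scale(spec, t))
    rel = points - np.asarray(spec.center)
    if spec.kind == "affine_contraction":
        return -s * rel
    r2 = np.sum(rel**2, axis=1, keepdims=True)
    return -s * rel * np.exp(-r2 / (2 * spec.sigma**2))


def analytic_divergence(spec: MotionSpec, points: np.ndarray, t: float) -> np.ndarray:
    """Closed-form divergence of u*(·, t) at the given points (nondimensional)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    s = float(_scale(spec, t))
    if spec.kind == "affine_contraction":
        return np.full(points.shape[0], -2.0 * s)
    rel = points - np.asarray(spec.center)
    r2 = np.sum(rel**2, axis=1)
    return -s * np.exp(-r2 / (2 * spec.sigma**2)) * (2.0 - r2 / spec.sigma**2)


def ground_truth_trace(
    spec: MotionSpec, times: np.ndarray | None = None, points: np.ndarray | None = None
) -> np.ndarray:
    """Ground-truth trace D*(t): spatial mean of |div u*| at the given times.

    For the affine model this is exactly the amplitude waveform; otherwise
    |div*| is averaged over ``points`` (default: a dense 64×64 grid spanning
    the frame).
    """
    t = spec.times if times is None else np.asarray(times, dtype=float)
    if spec.kind == "affine_contraction" and points is None:
        return np.asarray(spec.amplitude(t), dtype=float)
    if points is None:
        gx = np.linspace(0, spec.width - 1, 64)
        gy = np.linspace(0, spec.height - 1, 64)
        X, Y = np.meshgrid(gx, gy)
        points = np.column_stack([X.ravel(), Y.ravel()])
    return np.array([np.mean(np.abs(analytic_divergence(spec, points, tk))) for tk in t])


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference values for a MotionSpec recording."""

    t: np.ndarray
    trace: np.ndarray
    d_peak: float
    d_mean: float
    t_cycle: float
    t_contract: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "D_peak": self.d_peak,
                    "D_mean": self.d_mean,
                    "T_cycle": self.t_cycle,
                    "T_contract": self.t_contract,
                },
                indent=2,
            )
        )

    def trace_to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "D_star": self.trace}).to_csv(path, index=False)


def ground_truth(spec: MotionSpec, oracle_rate: float = 10_000.0) -> GroundTruth:
    """Dense-sampling reference metrics for a recording.

    D*(t) is sampled over one full period at ``oracle_rate`` (Hz) to obtain
    the continuous-time D_peak*, D_mean*, and the above-threshold contraction
    time T_contract* (time per cycle with D* strictly above 0.1·D_peak*);
    T_cycle* is the prescribed period.
    """
    t_dense = np.arange(0.0, spec.period, 1.0 / oracle_rate)
    d_dense = ground_truth_trace(spec, t_dense)
    d_peak = float(d_dense.max())
    d_mean = float(d_dense.mean())
    t_contract = float(np.sum(d_dense > 0.1 * d_peak) / oracle_rate)
    return GroundTruth(
        t=spec.times,
        trace=ground_truth_trace(spec),
        d_peak=d_peak,
        d_mean=d_mean,
        t_cycle=spec.period,
        t_contract=t_contract,
    )


def _inverse_map(spec: MotionSpec, X: np.ndarray, Y: np.ndarray, t: float):
    """Source coordinates x such that x + u*(x, t) equals the target (X, Y)."""
    s = float(_scale(spec, t))
    cx, cy = spec.center
    if spec.kind == "affine_contraction":
        # y = x - s (x - c)  =>  x = c + (y - c) / (1 - s), exact
        return cx + (X - cx) / (1.0 - s), cy + (Y - cy) / (1.0 - s)
    # fixed-point iteration x <- y - u*(x); converges fast for |s| << 1
    Xs, Ys = X, Y
    for _ in range(4):
        relx, rely = Xs - cx, Ys - cy
        w = np.exp(-(relx**2 + rely**2) / (2 * spec.sigma**2))
        Xs = X + s * relx * w
        Ys = Y + s * rely * w
    return Xs, Ys


def render_beating_video(
    texture: np.ndarray,
    spec: MotionSpec,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    interp_order: int = 1,
):
    """Warp the texture through the prescribed motion, one frame per time step.

    Frame k samples the texture by inverse mapping with u*(·, t_k) (bilinear
    by default, ``interp_order=3`` for cubic), then adds zero-mean Gaussian
    intensity noise of scale ``noise_sigma``.  At rest (amplitude zero) with
    zero noise a frame is bit-identical to the texture.
    """
    from .piv import FrameStack

    texture = np.asarray(texture, dtype=float)
    if texture.shape[0] < spec.height or texture.shape[1] < spec.width:
        raise ValueError("texture smaller than the requested frame")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=float)
    crop = texture[: spec.height, : spec.width]
    for k, tk in enumerate(spec.times):
        if float(spec.amplitude(tk)) == 0.0:
            frame = crop.copy()
        else:
            Xs, Ys = _inverse_map(spec, X, Y, tk)
            frame = map_coordinates(texture, [Ys, Xs], order=interp_order, mode="mirror")
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, frame.shape)
        frames[k] = frame
    return FrameStack(frames=frames, frame_rate=spec.frame_rate)


def simulate_cq_table(
    group_means: dict[str, float],
    sd: float = 0.3,
    n_per_group: int = 3,
    seed: int = 0,
    *,
    target_assay: str = "miR-486",
    control_assay: str = "U6",
    control_mean: float = 20.0,
) -> CqTable:
    """Draw per-sample Cq values around the given target-assay group means.

    Each sample also receives an endogenous-control Cq drawn around a
    ``control_mean`` common to all groups, so group ΔΔCt equals the
    difference of target group means.  Deterministic per seed.
    """
    if not group_means:
        raise ValueError("group_means must not be empty")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in group_means.items():
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            rows.append((sample, group, target_assay, mean + rng.normal(0, sd) if sd else mean))
            rows.append(
                (sample, group, control_assay, control_mean + rng.normal(0, sd) if sd else control_mean)
            )
    data = pd.DataFrame(rows, columns=["sample", "group", "assay", "cq"])
    return CqTable(data=data, target_assay=target_assay, control_assay=control_assay)
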