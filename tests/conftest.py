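import dataclasses

import numpy as np
import pytest

import cardiomotion as cm


@pytest.fixture(scope="session")
def texture128():
    return cm.make_speckle_texture(128, 128, n_speckles=900, speckle_sigma=1.3, seed=1)


@pytest.fixture(scope="session")
def spec_small():
    """Down-scaled default regime: 128 px, 3.3 s at 20 Hz, three beats."""
    return cm.MotionSpec(
        kind="affine_contraction",
        center=(64.0, 64.0),
        period=1.1,
        peak_divergence=0.02,
        rest_fraction=0.7,
        frame_rate=20.0,
        n_frames=66,
        width=128,
        height=128,
    )


@pytest.fixture(scope="session")
def stack_clean(texture128, spec_small):
    return cm.render_beating_video(texture128, spec_small, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def stack_noisy(texture128, spec_small):
    return cm.render_beating_video(texture128, spec_small, noise_sigma=0.01, seed=3)


@pytest.fixture(scope="session")
def small_run(stack_noisy, spec_small):
    """Reference selection, displacement series, trace, and metrics — shared
    across modules to avoid recomputing the PIV pass."""
    params = cm.PivParams()
    ref = cm.select_reference_frame(stack_noisy, dataclasses.replace(params, overlap=0))
    fields = cm.displacement_series(stack_noisy, ref, params)
    trace = cm.contractility_trace(fields)
    peaks = cm.detect_beats(trace)
    metrics = cm.compute_metrics(trace, peaks)
    return dict(ref=ref, fields=fields, trace=trace, peaks=peaks, metrics=metrics)


@pytest.fixture(scope="session")
def static_stack(texture128):
    frames = np.repeat(texture128[None], 3, axis=0)
    return cm.FrameStack(frames=frames, frame_rate=20.0)


def make_field(nx=7, ny=7, spacing=16.0, ufunc=None, vfunc=None, t=0.0):
    """DisplacementField on a regular grid from coordinate functions of (x, y)."""
    gx = spacing / 2 + spacing * np.arange(nx)
    gy = spacing / 2 + spacing * np.arange(ny)
    X, Y = np.meshgrid(gx, gy)
    u = ufunc(X, Y) if ufunc else np.zeros_like(X)
    v = vfunc(X, Y) if vfunc else np.zeros_like(X)
    return cm.DisplacementField(
        grid_x=gx, grid_y=gy, u=u, v=v, valid=np.ones_like(u, dtype=bool), t=t
    )
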