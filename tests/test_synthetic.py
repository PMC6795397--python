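"""Generator checks: determinism, analytic fields, warping, Cq simulation."""

import dataclasses

import numpy as np
import pytest

import cardiomotion as cm
from cardiomotion.synthetic import MotionSpec, analytic_divergence


class TestSpeckleTexture:
    def test_fixed_seed_is_bit_identical(self):
        a = cm.make_speckle_texture(256, 256, 2000, 1.5, seed=1)
        b = cm.make_speckle_texture(256, 256, 2000, 1.5, seed=1)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_different_seed_differs(self):
        a = cm.make_speckle_texture(128, 128, 500, 1.5, seed=1)
        b = cm.make_speckle_texture(128, 128, 500, 1.5, seed=2)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(width=32, height=128), dict(n_speckles=0), dict(speckle_sigma=0.0)],
    )
    def test_preconditions(self, kwargs):
        args = dict(width=128, height=128, n_speckles=800, speckle_sigma=1.0, seed=7)
        args.update(kwargs)
        with pytest.raises(ValueError):
            cm.make_speckle_texture(**args)

    def test_texture_is_nonuniform(self):
        img = cm.make_speckle_texture(128, 128, 800, 1.0, seed=7)
        assert img.var() > 1e-4


class TestMotionSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(period=0.0),
            dict(peak_divergence=-0.01),
            dict(rest_fraction=1.0),
            dict(rest_fraction=-0.1),
            dict(frame_rate=0.0),
            dict(n_frames=0),
            dict(kind="spiral"),
            dict(waveform="square"),
            dict(waveform="custom", custom_samples=(0.5, 0.1)),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotionSpec(**kwargs)

    @pytest.mark.parametrize("waveform", ["sin2_pulse", "triangle"])
    def test_starts_at_rest_and_is_periodic(self, waveform):
        spec = MotionSpec(waveform=waveform, period=1.1, rest_fraction=0.3)
        assert spec.amplitude(0.0) == 0.0
        t = np.linspace(0, 1.1, 23)
        assert np.allclose(spec.amplitude(t), spec.amplitude(t + 3 * 1.1), atol=1e-12)
        assert spec.amplitude(t).max() <= spec.peak_divergence + 1e-12

    def test_rest_segment_is_flat(self):
        spec = MotionSpec(period=1.0, rest_fraction=0.4)
        t = np.linspace(0, 0.399, 50)
        assert np.all(spec.amplitude(t) == 0.0)

    def test_yaml_round_trip(self, tmp_path):
        spec = MotionSpec(kind="radial_gaussian", sigma=50.0, center=(40.0, 60.0))
        spec.to_yaml(tmp_path / "m.yaml")
        assert MotionSpec.from_yaml(tmp_path / "m.yaml") == spec


class TestAnalyticDisplacement:
    def test_rest_phase_is_zero(self, spec_small):
        pts = np.array([[10.0, 10.0], [100.0, 30.0]])
        u = cm.analytic_displacement(spec_small, pts, t=0.0)
        assert np.all(u == 0.0)

    def test_affine_linear_field(self):
        # amplitude 0.02 => s = 0.01; u = -s (x - c)
        spec = MotionSpec(rest_fraction=0.0, period=1.0, peak_divergence=0.02,
                          center=(64.0, 64.0), width=128, height=128)
        t_peak = 0.5  # sin^2 pulse maximum
        u_center = cm.analytic_displacement(spec, [(64.0, 64.0)], t_peak)
        assert np.allclose(u_center, 0.0)
        u_off = cm.analytic_displacement(spec, [(74.0, 64.0)], t_peak)
        assert np.allclose(u_off, [[-0.1, 0.0]], atol=1e-12)

    def test_point_outside_frame_rejected(self, spec_small):
        with pytest.raises(ValueError):
            cm.analytic_displacement(spec_small, [(200.0, 10.0)], t=0.5)
        with pytest.raises(ValueError):
            cm.analytic_displacement(spec_small, [(10.0, 10.0)], t=1e6)

    def test_radial_divergence_matches_finite_difference(self):
        spec = MotionSpec(kind="radial_gaussian", sigma=40.0, rest_fraction=0.0,
                          period=1.0, center=(64.0, 64.0), width=128, height=128)
        t = 0.37
        probes = np.array([[64.0, 64.0], [80.0, 64.0], [50.0, 90.0], [30.0, 30.0], [100.0, 70.0]])
        h = 1e-4
        div_fd = []
        for x, y in probes:
            ux = cm.analytic_displacement(spec, [(x + h, y), (x - h, y)], t, check_bounds=False)
            vy = cm.analytic_displacement(spec, [(x, y + h), (x, y - h)], t, check_bounds=False)
            div_fd.append((ux[0, 0] - ux[1, 0]) / (2 * h) + (vy[0, 1] - vy[1, 1]) / (2 * h))
        assert np.allclose(div_fd, analytic_divergence(spec, probes, t), atol=1e-6)

    def test_affine_ground_truth_self_consistency(self, spec_small):
        # dense |div| sampling equals the amplitude waveform for affine motion
        gx = np.linspace(0, 127, 40)
        X, Y = np.meshgrid(gx, gx)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        for t in [0.85, 0.95, 1.0]:
            dense = np.mean(np.abs(analytic_divergence(spec_small, pts, t)))
            assert abs(dense - spec_small.amplitude(t)) < 1e-6


class TestRenderVideo:
    def test_zero_amplitude_reproduces_texture(self, texture128):
        spec = MotionSpec(peak_divergence=0.0, n_frames=5, width=128, height=128,
                          center=(64.0, 64.0))
        stack = cm.render_beating_video(texture128, spec, noise_sigma=0.0, seed=0)
        for k in range(5):
            assert np.array_equal(stack.frames[k], texture128)

    def test_one_period_apart_frames_identical(self, texture128):
        spec = MotionSpec(period=1.0, frame_rate=20.0, n_frames=25, rest_fraction=0.3,
                          width=128, height=128, center=(64.0, 64.0))
        stack = cm.render_beating_video(texture128, spec, noise_sigma=0.0, seed=0)
        assert np.array_equal(stack.frames[0], stack.frames[20])
        assert np.array_equal(stack.frames[2], stack.frames[22])

    def test_contraction_moves_intensity(self, stack_clean, spec_small):
        amp = spec_small.amplitude(spec_small.times)
        mid = int(np.argmax(amp))  # most contracted frame
        rest = 0
        d_mid = np.abs(stack_clean.frames[mid] - stack_clean.frames[mid - 1]).mean()
        d_rest = np.abs(stack_clean.frames[rest + 1] - stack_clean.frames[rest]).mean()
        assert d_mid > d_rest

    def test_seeded_noise_is_deterministic(self, texture128, spec_small):
        a = cm.render_beating_video(texture128, spec_small, noise_sigma=0.02, seed=9)
        b = cm.render_beating_video(texture128, spec_small, noise_sigma=0.02, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_negative_noise_rejected(self, texture128, spec_small):
        with pytest.raises(ValueError):
            cm.render_beating_video(texture128, spec_small, noise_sigma=-0.1, seed=0)

    def test_texture_smaller_than_frame_rejected(self, spec_small):
        small = cm.make_speckle_texture(64, 64, 100, 1.0, seed=0)
        with pytest.raises(ValueError):
            cm.render_beating_video(small, spec_small, seed=0)

    def test_tiff_round_trip(self, tmp_path, stack_clean):
        stack_clean.to_tiff(tmp_path / "v.tif")
        back = cm.FrameStack.from_tiff(tmp_path / "v.tif", frame_rate=20.0)
        assert back.frames.shape == stack_clean.frames.shape
        assert np.abs(back.frames - np.clip(stack_clean.frames, 0, 1)).max() < 1e-4


class TestSimulateCq:
    def test_sd_zero_gives_exact_means(self):
        tbl = cm.simulate_cq_table({"ctl": 9.46, "hlhs": 7.17}, sd=0.0, n_per_group=3, seed=1)
        target = tbl.data[tbl.data["assay"] == tbl.target_assay]
        assert np.all(target[target["group"] == "ctl"]["cq"] == 9.46)
        assert np.all(target[target["group"] == "hlhs"]["cq"] == 7.17)

    def test_downstream_fold_change_matches_printed_means(self):
        tbl = cm.simulate_cq_table({"ctl": 9.46, "hlhs": 7.17}, sd=0.0, n_per_group=3, seed=1)
        dct = cm.normalize_dct(tbl)
        fold = cm.fold_change_ddct(
            dct[dct["group"] == "hlhs"]["dct"], dct[dct["group"] == "ctl"]["dct"]
        )
        assert fold == pytest.approx(2**2.29, rel=1e-12)

    def test_sample_means_converge(self):
        tbl = cm.simulate_cq_table({"a": 5.0, "b": 8.0}, sd=0.3, n_per_group=10_000, seed=1)
        target = tbl.data[tbl.data["assay"] == tbl.target_assay]
        for group, mean in [("a", 5.0), ("b", 8.0)]:
            assert abs(target[target["group"] == group]["cq"].mean() - mean) < 0.02

    def test_determinism_and_empty_group_error(self):
        a = cm.simulate_cq_table({"x": 1.0}, sd=0.5, n_per_group=4, seed=11)
        b = cm.simulate_cq_table({"x": 1.0}, sd=0.5, n_per_group=4, seed=11)
        assert a.data.equals(b.data)
        with pytest.raises(ValueError):
            cm.simulate_cq_table({}, sd=0.1, n_per_group=2, seed=0)
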