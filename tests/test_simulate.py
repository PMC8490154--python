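"""Simulator: Brownian tracks, PSF rendering, backgrounds, fixtures."""

import numpy as np
import pytest

from mspt.simulate import (SimulationConfig, gen_background,
                           gen_landing_events, gen_mass_trace,
                           gen_trajectories, render_ratiometric_video,
                           synthesize_camera_video)
from mspt.video import CameraVideo


def small_config(**kw):
    defaults = dict(fov_px=(64, 32), n_frames=50, n_particles=5, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestTrajectories:
    def test_zero_diffusion_is_static(self):
        tracks = gen_trajectories(small_config(), 0.0)
        for tr in tracks:
            assert np.all(tr.x_px == tr.x_px[0])
            assert np.all(tr.y_px == tr.y_px[0])

    def test_step_variance_matches_2ddt(self):
        # D = 1 um^2/s, dt = 5 ms -> per-axis step variance 0.01 um^2
        cfg = SimulationConfig(fov_px=(64, 32), n_frames=20001, n_particles=5,
                               seed=3)
        tracks = gen_trajectories(cfg, 1.0)
        steps = []
        for tr in tracks:
            dx = np.diff(tr.x_px) * cfg.pixel_size_um
            dx = dx[np.abs(dx) < 10]  # drop periodic wrap jumps
            steps.append(dx)
        steps = np.concatenate(steps)
        assert steps.size > 1e5 - 1000
        var = np.var(steps)
        se = np.sqrt(2.0 / steps.size) * 0.01
        assert abs(var - 0.01) < 3 * se

    def test_extended_area_is_four_fov(self):
        cfg = SimulationConfig(fov_px=(128, 35), n_frames=2, n_particles=4000,
                               seed=5)
        tracks = gen_trajectories(cfg, 0.0)
        xs = np.array([t.x_px[0] for t in tracks])
        ys = np.array([t.y_px[0] for t in tracks])
        # both axes doubled: 256 x 70 px, FOV centred
        assert xs.min() >= -64 and xs.max() < 192
        assert ys.min() >= -17.5 and ys.max() < 52.5
        assert xs.max() - xs.min() > 0.9 * 256
        assert ys.max() - ys.min() > 0.9 * 70

    def test_periodic_wrap_keeps_particles_inside(self):
        cfg = small_config(n_frames=500)
        for tr in gen_trajectories(cfg, 5.0):
            assert np.all(tr.x_px >= -32) and np.all(tr.x_px < 96)
            assert np.all(tr.y_px >= -16) and np.all(tr.y_px < 48)

    def test_ensemble_msd_grows_as_4ddt(self):
        cfg = SimulationConfig(fov_px=(64, 32), n_frames=21, n_particles=1500,
                               seed=9)
        d_true = 0.5
        tracks = gen_trajectories(cfg, d_true)
        for lag in (1, 5, 10):
            disp = []
            for tr in tracks:
                dx = (tr.x_px[lag:] - tr.x_px[:-lag]) * cfg.pixel_size_um
                dy = (tr.y_px[lag:] - tr.y_px[:-lag]) * cfg.pixel_size_um
                keep = (np.abs(dx) < 3) & (np.abs(dy) < 3)  # unwrapped pairs
                disp.append(dx[keep] ** 2 + dy[keep] ** 2)
            msd = np.mean(np.concatenate(disp))
            expected = 4 * d_true * cfg.frame_time_s * lag
            assert msd == pytest.approx(expected, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gen_trajectories(small_config(), np.inf)
        with pytest.raises(ValueError):
            SimulationConfig(fov_px=(64, 32), n_frames=0, n_particles=1)

    def test_seeded_reproducibility(self):
        a = gen_trajectories(small_config(seed=7), 1.0)
        b = gen_trajectories(small_config(seed=7), 1.0)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_px, tb.x_px)
            np.testing.assert_array_equal(ta.y_px, tb.y_px)


class TestRender:
    def test_static_particle_dip_amplitude(self):
        cfg = small_config(n_particles=1, n_frames=3)
        tracks = gen_trajectories(cfg, 0.0)
        tracks[0].x_px[:] = 20.0  # pixel centre: peak sampling is exact
        tracks[0].y_px[:] = 16.0
        ratio = render_ratiometric_video(tracks, cfg)
        assert ratio.frames[0].min() == pytest.approx(-tracks[0].contrast,
                                                      rel=1e-12)

    def test_no_tracks_all_zero(self):
        ratio = render_ratiometric_video([], small_config())
        assert np.all(ratio.frames == 0)

    def test_colocated_particles_add(self):
        cfg = small_config(n_particles=2, n_frames=2)
        tracks = gen_trajectories(cfg, 0.0)
        for tr in tracks:
            tr.x_px[:] = 20.0
            tr.y_px[:] = 16.0
        ratio = render_ratiometric_video(tracks, cfg)
        assert ratio.frames[0].min() == pytest.approx(-2 * tracks[0].contrast,
                                                      rel=1e-12)

    def test_oversized_psf_rejected(self):
        cfg = small_config(psf_sigma_px=20.0)
        with pytest.raises(ValueError):
            render_ratiometric_video([], cfg)


class TestSynthesize:
    def test_zero_contrast_is_identity(self):
        cfg = small_config()
        ratio = render_ratiometric_video([], cfg)
        bg = gen_background(cfg, seed=1)
        out = synthesize_camera_video(ratio, bg)
        np.testing.assert_array_equal(out.frames, bg.frames)

    def test_pixelwise_arithmetic(self):
        cfg = small_config(n_frames=1)
        ratio = render_ratiometric_video([], cfg)
        ratio.frames[0, 5, 5] = -0.5
        bg = CameraVideo(np.full((1, 32, 64), 1000.0))
        out = synthesize_camera_video(ratio, bg)
        assert out.frames[0, 5, 5] == 500.0

    def test_round_trip_inverts_exactly(self):
        cfg = small_config(n_particles=3, n_frames=10)
        tracks = gen_trajectories(cfg, 1.0)
        ratio = render_ratiometric_video(tracks, cfg)
        bg = gen_background(cfg, noise_free=True)
        out = synthesize_camera_video(ratio, bg)
        recovered = out.frames / bg.frames - 1.0
        np.testing.assert_allclose(recovered, ratio.frames, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        ratio = render_ratiometric_video([], small_config(n_frames=5))
        bg = gen_background(small_config(n_frames=6), seed=0)
        with pytest.raises(ValueError):
            synthesize_camera_video(ratio, bg)


class TestBackgroundGenerator:
    def test_poisson_relative_noise(self):
        cfg = small_config(photon_level=1e6, n_frames=60)
        bg = gen_background(cfg, seed=4)
        rel_sd = bg.frames.std() / bg.frames.mean()
        assert rel_sd == pytest.approx(1e-3, rel=0.1)

    def test_noise_free_limit_constant(self):
        bg = gen_background(small_config(), noise_free=True)
        assert np.all(bg.frames == bg.frames.flat[0])

    def test_temporal_mean_tracks_fixed_pattern(self, rng):
        cfg = small_config(photon_level=1e5, n_frames=400)
        pattern = 1.0 + 0.05 * rng.standard_normal((32, 64))
        bg = gen_background(cfg, seed=6, fixed_pattern=pattern)
        mean = bg.frames.mean(axis=0)
        np.testing.assert_allclose(mean, 1e5 * pattern, rtol=0.01)

    def test_invalid_photon_level(self):
        with pytest.raises(ValueError):
            SimulationConfig(fov_px=(8, 8), n_frames=2, n_particles=1,
                             photon_level=-1.0)


class TestLandingEvents:
    def test_default_constraints_hold_pairwise(self):
        cfg = SimulationConfig(fov_px=(128, 35), n_frames=1000, n_particles=1,
                               seed=8)
        events = gen_landing_events(cfg, 100, 12.0, 26)
        placed = [(t.x_px[-1], t.y_px[-1], t.landing_frame) for t in events]
        assert len(placed) == 100
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                xi, yi, fi = placed[i]
                xj, yj, fj = placed[j]
                spatial = np.hypot(xi - xj, yi - yj)
                assert spatial >= 12.0 or abs(fi - fj) >= 26

    def test_single_event_trivially_valid(self):
        cfg = small_config(n_frames=100)
        events = gen_landing_events(cfg, 1, 12.0, 26)
        assert len(events) == 1

    def test_unsatisfiable_constraints_fail_loudly(self):
        cfg = SimulationConfig(fov_px=(20, 20), n_frames=10, n_particles=1,
                               seed=0)
        with pytest.raises(RuntimeError):
            gen_landing_events(cfg, 500, 50.0, 1000, max_tries=50)

    def test_events_immobile_after_landing(self):
        cfg = small_config(n_frames=200)
        for tr in gen_landing_events(cfg, 5, 12.0, 26, seed=2):
            f = tr.landing_frame
            assert np.all(tr.x_px[f:] == tr.x_px[f])


class TestMassTrace:
    def test_noise_free_two_level(self):
        trace = gen_mass_trace([66.0, 132.0], [10, 5], 0.0)
        assert np.all(trace[:10] == 66.0) and np.all(trace[10:] == 132.0)
        assert trace.size == 15

    def test_noise_sd_matches(self):
        trace = gen_mass_trace([100.0], [20000], 28.0, seed=3)
        assert trace.std() == pytest.approx(28.0, rel=0.05)

    def test_single_plateau_constant_mean(self):
        trace = gen_mass_trace([66.0], [5000], 5.0, seed=4)
        assert trace.mean() == pytest.approx(66.0, abs=0.5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            gen_mass_trace([1.0], [5], -1.0)
        with pytest.raises(ValueError):
            gen_mass_trace([1.0, 2.0], [5], 1.0)
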