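"""Particle simulator: motion statistics, turnover, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cortexflow as cf
from cortexflow.particle_sim import RENDER_PAD_PX


def displacements(traj, lag=1):
    """Per-axis lag-`lag` displacements of every track (no flow frame)."""
    g = traj.data.sort_values(["particle_id", "frame"])
    lead = g.groupby("particle_id")[["frame", "x_um", "y_um"]].shift(-lag)
    ok = (lead["frame"] - g["frame"]) == lag
    return ((lead["x_um"] - g["x_um"])[ok].to_numpy(),
            (lead["y_um"] - g["y_um"])[ok].to_numpy())


class TestTrajectories:
    def test_no_motion_sources_positions_constant(self):
        cfg = cf.SimulationConfig(n_particles=20, D=0.0, k_off=0.0, duration=2.0)
        traj, _ = cf.simulate_trajectories(cfg)
        spread = traj.data.groupby("particle_id")[["x_um", "y_um"]].agg(np.ptp)
        assert (spread.to_numpy() == 0).all()

    def test_single_frame_msd_matches_2dtau(self):
        # <dy²> = 2Dτ per axis for pure diffusion
        cfg = cf.SimulationConfig(n_particles=500, D=0.1, k_off=0.0,
                                  frame_interval=0.1, duration=2.0, seed=7)
        traj, _ = cf.simulate_trajectories(cfg)
        dx, dy = displacements(traj)
        expected = 2 * 0.1 * 0.1
        for d in (dx, dy):
            msd = (d**2).mean()
            se = (d**2).std() / np.sqrt(len(d))
            assert abs(msd - expected) < 3 * se

    @pytest.mark.parametrize("lag", [1, 2, 3, 4, 5])
    def test_msd_linear_in_lag(self, lag):
        cfg = cf.SimulationConfig(n_particles=400, D=0.05, k_off=0.0,
                                  frame_interval=0.1, duration=3.0, seed=11)
        traj, _ = cf.simulate_trajectories(cfg)
        dx, dy = displacements(traj, lag)
        msd_2d = (dx**2 + dy**2).mean()
        expected = 4 * 0.05 * 0.1 * lag
        assert msd_2d == pytest.approx(expected, rel=0.1)

    def test_mean_drift_and_recovered_coupling(self):
        # drift 0.05 µm/s at τ = 0.5 s ⇒ <Δx> ≈ 0.025 µm; against an imposed
        # 0.1 µm/s flow the fitted coupling coefficient is 0.5
        cfg = cf.SimulationConfig(n_particles=2000, D=0.05, k_off=0.0,
                                  v_parallel=0.05, duration=0.5,
                                  frame_interval=0.1, seed=3)
        traj, _ = cf.simulate_trajectories(cfg)
        dx, _ = displacements(traj, 5)
        se = dx.std() / np.sqrt(len(dx))
        assert abs(dx.mean() - 0.025) < 3 * se
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        samples = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(samples)
        assert est.cc == pytest.approx(0.5, abs=3 * est.se_cc)

    def test_isotropy_without_advection(self):
        cfg = cf.SimulationConfig(n_particles=500, D=0.1, k_off=0.0,
                                  duration=2.0, seed=13)
        traj, _ = cf.simulate_trajectories(cfg)
        for d in displacements(traj):
            assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d))

    def test_constant_occupancy_with_turnover(self):
        cfg = cf.SimulationConfig(n_particles=50, D=0.05, k_off=0.5,
                                  duration=10.0, seed=5)
        traj, _ = cf.simulate_trajectories(cfg)
        counts = traj.data.groupby("frame").size()
        assert len(counts) == cfg.n_frames
        assert (counts == 50).all()

    def test_no_particle_reappears_after_its_last_frame(self):
        cfg = cf.SimulationConfig(n_particles=30, D=0.05, k_off=0.3,
                                  duration=10.0, seed=5)
        traj, _ = cf.simulate_trajectories(cfg)
        spans = traj.data.groupby("particle_id")["frame"].agg(["min", "max", "size"])
        assert ((spans["max"] - spans["min"] + 1) == spans["size"]).all()

    def test_lifetimes_are_exponential(self):
        # KS non-rejection at alpha = 0.01, n = 10^4 drawn lifetimes
        cfg = cf.SimulationConfig(n_particles=400, D=0.0, k_off=0.2,
                                  duration=200.0, frame_interval=0.1, seed=17)
        _, truth = cf.simulate_trajectories(cfg)
        lifetimes = truth["lifetime_s"].to_numpy()
        lifetimes = lifetimes[np.isfinite(lifetimes)][:10000]
        assert len(lifetimes) >= 10000
        _, p = stats.kstest(lifetimes, "expon", args=(0, 1 / 0.2))
        assert p > 0.01

    def test_seed_determinism(self):
        cfg = cf.SimulationConfig(n_particles=40, D=0.1, k_off=0.2,
                                  duration=5.0, seed=99)
        t1, g1 = cf.simulate_trajectories(cfg)
        t2, g2 = cf.simulate_trajectories(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(g1, g2)

    def test_lognormal_diffusivity_spread(self):
        cfg = cf.SimulationConfig(n_particles=4000, D=0.1, cv_D=0.5,
                                  k_off=0.0, duration=0.2, seed=23)
        _, truth = cf.simulate_trajectories(cfg)
        d = truth["D_um2_s"]
        assert (d > 0).all()
        assert d.mean() == pytest.approx(0.1, rel=0.05)
        assert d.std() / d.mean() == pytest.approx(0.5, rel=0.1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            cf.SimulationConfig(D=-1.0)
        with pytest.raises(ValueError):
            cf.SimulationConfig(frame_interval=0.0)
        with pytest.raises(ValueError):
            cf.SimulationConfig(duration=0.01, frame_interval=0.1)

    def test_csv_round_trip(self, tmp_path):
        cfg = cf.SimulationConfig(n_particles=10, duration=1.0, seed=1)
        traj, _ = cf.simulate_trajectories(cfg)
        traj.to_csv(tmp_path / "t.csv")
        back = cf.TrajectorySet.from_csv(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(traj.data, back.data)


class TestRendering:
    def test_background_only(self):
        cfg = cf.SimulationConfig(n_particles=0, long_axis=10.0, short_axis=10.0,
                                  duration=0.5, background_mean=100.0,
                                  background_noise_sd=5.0, seed=2)
        traj, _ = cf.simulate_trajectories(cfg)
        stack = cf.render_images(traj, cfg)
        n_px = stack.frames[0].size
        se = 5.0 / np.sqrt(n_px)
        for frame in stack.frames:
            assert abs(frame.mean() - 100.0) < 3 * se

    def test_six_pixel_padding_rule(self):
        cfg = cf.SimulationConfig(n_particles=5, D=0.0, k_off=0.0,
                                  long_axis=20.0, short_axis=20.0,
                                  pixel_size=0.1, duration=0.5, seed=4)
        traj, _ = cf.simulate_trajectories(cfg)
        stack = cf.render_images(traj, cfg)
        assert stack.frames.shape[1:] == (200 + 2 * RENDER_PAD_PX,
                                          200 + 2 * RENDER_PAD_PX)

    def test_spot_centroid_at_subpixel_truth(self):
        cfg = cf.SimulationConfig(n_particles=0, long_axis=10.0, short_axis=10.0,
                                  spot_amplitude=1000.0, background_mean=10.0,
                                  background_noise_sd=0.5, seed=6)
        df = pd.DataFrame({"particle_id": [0], "frame": [0], "time_s": [0.0],
                           "x_um": [5.337], "y_um": [4.182], "intensity": [1000.0]})
        stack = cf.render_images(cf.TrajectorySet(df), cfg)
        img = stack.frames[0] - 10.0
        x_px_truth = (5.337 - stack.origin[0]) / cfg.pixel_size
        y_px_truth = (4.182 - stack.origin[1]) / cfg.pixel_size
        # intensity-weighted centroid around the brightest pixel
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        win = img[iy - 5:iy + 6, ix - 5:ix + 6]
        gy, gx = np.mgrid[iy - 5:iy + 6, ix - 5:ix + 6]
        cx = (win * gx).sum() / win.sum()
        cy = (win * gy).sum() / win.sum()
        assert abs(cx - x_px_truth) < 0.1
        assert abs(cy - y_px_truth) < 0.1

    def test_tiff_round_trip(self, tmp_path):
        cfg = cf.SimulationConfig(n_particles=3, duration=0.3, long_axis=5.0,
                                  short_axis=5.0, seed=8)
        traj, _ = cf.simulate_trajectories(cfg)
        stack = cf.render_images(traj, cfg)
        stack.to_tiff(tmp_path / "s.tif")
        back = cf.ImageStack.from_tiff(tmp_path / "s.tif")
        assert back.frames.shape == stack.frames.shape
        assert back.pixel_size == stack.pixel_size
        assert back.origin == pytest.approx(stack.origin)
        np.testing.assert_allclose(back.frames, stack.frames, rtol=1e-6)


class TestCortexTexture:
    def test_zero_flow_frames_identical_up_to_noise(self):
        flow = cf.FlowField.uniform(0.0, 0.0, extent=(10.0, 10.0))
        cfg = cf.SimulationConfig(n_particles=0, long_axis=10.0, short_axis=10.0,
                                  background_noise_sd=1.0, spot_amplitude=100.0,
                                  duration=3.0, frame_interval=1.0, seed=9)
        stack = cf.render_cortex_texture(flow, cfg, n_frames=3)
        diff = stack.frames[2] - stack.frames[0]
        assert diff.std() < 5 * 1.0  # noise only, no structural change

    def test_untrackable_flow_rejected(self):
        flow = cf.FlowField.uniform(10.0, 0.0, extent=(10.0, 10.0))
        cfg = cf.SimulationConfig(n_particles=0, long_axis=10.0, short_axis=10.0,
                                  pixel_size=0.1, frame_interval=1.0, seed=9)
        with pytest.raises(ValueError, match="untrackable|exceeds"):
            cf.render_cortex_texture(flow, cfg, n_frames=2)
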