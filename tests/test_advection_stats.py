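"""Displacement projection, coupling-coefficient fitting, diffusivity and
detection-power estimators."""

import numpy as np
import pandas as pd
import pytest

import cortexflow as cf
from cortexflow.advection_stats import detection_limit, detection_power


def make_traj(positions, dt=0.1):
    """positions: array (n_particles, n_frames, 2) in µm."""
    n, nf, _ = positions.shape
    df = pd.DataFrame({
        "particle_id": np.repeat(np.arange(n), nf),
        "frame": np.tile(np.arange(nf), n),
        "x_um": positions[:, :, 0].ravel(),
        "y_um": positions[:, :, 1].ravel(),
    })
    df["time_s"] = df["frame"] * dt
    df["intensity"] = 100.0
    return cf.TrajectorySet(df[["particle_id", "frame", "time_s",
                                "x_um", "y_um", "intensity"]])


def advected_sim(D, flow_speed=0.1, n=1000, seed=0, duration=0.5):
    cfg = cf.SimulationConfig(n_particles=n, D=D, k_off=0.0,
                              v_parallel=flow_speed, duration=duration,
                              frame_interval=0.1, seed=seed)
    traj, _ = cf.simulate_trajectories(cfg)
    flow = cf.FlowField.uniform(flow_speed, 0.0, extent=(300.0, 300.0), spacing=50.0)
    return traj, flow


class TestProjection:
    def test_flow_aligned_displacement_unchanged(self):
        pos = np.array([[[0.0, 0.0], [0.05, 0.02]]])
        traj = make_traj(pos)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(10.0, 10.0))
        s = cf.project_displacements(traj, flow, tau_frames=1)
        assert s["dx_um"].iloc[0] == pytest.approx(0.05)
        assert s["dy_um"].iloc[0] == pytest.approx(0.02)

    def test_rotated_flow_rotates_components(self):
        pos = np.array([[[0.0, 0.0], [0.05, 0.02]]])
        traj = make_traj(pos)
        flow = cf.FlowField.uniform(0.0, 0.1, extent=(10.0, 10.0))  # flow along +y
        s = cf.project_displacements(traj, flow, tau_frames=1)
        assert s["dx_um"].iloc[0] == pytest.approx(0.02)
        assert s["dy_um"].iloc[0] == pytest.approx(-0.05)

    def test_full_entrainment_means(self):
        traj, flow = advected_sim(D=0.05, seed=1)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        n = len(s)
        se = s["dx_um"].std() / np.sqrt(n)
        assert abs(s["dy_um"].mean()) < 3 * s["dy_um"].std() / np.sqrt(n)
        assert s["dx_um"].mean() == pytest.approx(0.1 * 0.5, abs=3 * se)

    def test_low_speed_steps_flagged(self):
        pos = np.zeros((1, 3, 2))
        traj = make_traj(pos)
        flow = cf.FlowField.uniform(0.001, 0.0, extent=(10.0, 10.0))
        s = cf.project_displacements(traj, flow, tau_frames=1)
        assert s["low_speed"].all()

    def test_lag_longer_than_tracks_warns_and_empty(self):
        pos = np.zeros((2, 3, 2))
        traj = make_traj(pos)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(10.0, 10.0))
        with pytest.warns(UserWarning, match="lag"):
            s = cf.project_displacements(traj, flow, tau_frames=10)
        assert len(s) == 0


class TestCouplingFit:
    def test_zero_drift_gives_zero_cc(self):
        # bead-like control: no drift against a 0.1 µm/s flow
        traj, _ = advected_sim(D=0.05, flow_speed=0.0, seed=2)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(s)
        assert est.cc == pytest.approx(0.0, abs=3 * est.se_cc)

    def test_full_entrainment_gives_unit_cc(self):
        traj, flow = advected_sim(D=0.01, seed=3)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(s)
        assert est.cc == pytest.approx(1.0, abs=3 * est.se_cc)

    def test_partial_drift_gives_half_cc(self):
        traj, _ = advected_sim(D=0.05, flow_speed=0.05, seed=4)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(s)
        assert est.cc == pytest.approx(0.5, abs=3 * est.se_cc)

    def test_histogram_fit_agrees_with_sample_mean(self):
        traj, flow = advected_sim(D=0.05, seed=5)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(s)
        hist_mean, _ = est.histogram_fit_parallel
        se = est.sigma_parallel / np.sqrt(est.n_steps)
        assert abs(hist_mean - est.v_parallel * est.tau) < se

    def test_zero_flow_cc_undefined(self):
        traj, _ = advected_sim(D=0.05, flow_speed=0.0, seed=6)
        flow = cf.FlowField.uniform(0.0, 0.0, extent=(300.0, 300.0), spacing=50.0)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        est = cf.fit_advection(s, include_low_speed=True)
        assert est.cc is None

    def test_too_few_samples_rejected(self):
        traj, flow = advected_sim(D=0.05, n=10, seed=7)
        s = cf.project_displacements(traj, flow, tau_frames=5)
        with pytest.raises(ValueError, match="too few"):
            cf.fit_advection(s, min_samples=200)

    def test_unbiased_over_repeats(self):
        # 100 independent simulations at D = 0.1, true cc = 1
        ccs = []
        for i in range(100):
            traj, flow = advected_sim(D=0.1, n=300, seed=1000 + i)
            s = cf.project_displacements(traj, flow, tau_frames=5)
            ccs.append(cf.fit_advection(s, min_samples=100).cc)
        assert 0.97 <= np.mean(ccs) <= 1.03

    @pytest.mark.parametrize("angle_deg", [30.0, 90.0, 215.0])
    def test_cc_invariant_under_global_rotation(self, angle_deg):
        traj, _ = advected_sim(D=0.02, seed=8, n=500)
        th = np.radians(angle_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        flow0 = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        s0 = cf.project_displacements(traj, flow0, tau_frames=5)
        cc0 = cf.fit_advection(s0).cc
        rot = traj.data.copy()
        xy = rot[["x_um", "y_um"]].to_numpy() @ R.T
        rot["x_um"], rot["y_um"] = xy[:, 0] + 500.0, xy[:, 1] + 500.0
        v_rot = R @ np.array([0.1, 0.0])
        flow_r = cf.FlowField.uniform(v_rot[0], v_rot[1],
                                      extent=(1000.0, 1000.0), spacing=100.0)
        s1 = cf.project_displacements(cf.TrajectorySet(rot), flow_r, tau_frames=5)
        cc1 = cf.fit_advection(s1).cc
        assert cc1 == pytest.approx(cc0, abs=1e-9)


class TestDiffusivity:
    def test_stationary_particle_zero(self):
        pos = np.zeros((1, 10, 2))
        est = cf.estimate_diffusivity(make_traj(pos), tau_frames=2, mode="2d")
        assert est["D_um2_s"].iloc[0] == 0.0

    def test_pooled_recovery_within_ten_percent(self):
        cfg = cf.SimulationConfig(n_particles=500, D=0.1, k_off=0.0,
                                  duration=1.5, frame_interval=0.1, seed=10)
        traj, _ = cf.simulate_trajectories(cfg)
        est = cf.estimate_diffusivity(traj, tau_frames=2, mode="2d")
        assert est["D_um2_s"].mean() == pytest.approx(0.1, rel=0.1)

    def test_perpendicular_mode_ignores_advection(self):
        traj, flow = advected_sim(D=0.05, seed=11, duration=1.0)
        est = cf.estimate_diffusivity(traj, flow, tau_frames=2, mode="perpendicular")
        assert est["D_um2_s"].mean() == pytest.approx(0.05, rel=0.1)

    def test_pure_advection_perpendicular_zero(self):
        traj, flow = advected_sim(D=0.0, seed=12, n=200)
        est = cf.estimate_diffusivity(traj, flow, tau_frames=2, mode="perpendicular")
        assert est["D_um2_s"].max() < 1e-12

    def test_perpendicular_requires_flow(self):
        pos = np.zeros((1, 10, 2))
        with pytest.raises(ValueError, match="flow"):
            cf.estimate_diffusivity(make_traj(pos), None, mode="perpendicular")


class TestBinning:
    def test_two_subpopulations_both_fully_coupled(self):
        # D = 0.01 and 0.1, both advected at the flow speed: coupling must
        # come out independent of diffusivity. One lag-5 step per particle
        # keeps the displacement samples independent.
        parts = []
        for j, D in enumerate((0.01, 0.1)):
            cfg = cf.SimulationConfig(n_particles=1500, D=D, k_off=0.0,
                                      v_parallel=0.1, duration=0.5,
                                      frame_interval=0.1, seed=20 + j)
            t, _ = cf.simulate_trajectories(cfg)
            d = t.data.copy()
            d["particle_id"] += 10000 * j
            parts.append(d)
        traj = cf.TrajectorySet(pd.concat(parts, ignore_index=True))
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        out = cf.bin_and_fit(traj, flow, "diffusivity",
                             bin_edges=[0.0, 0.05, 0.5], tau_frames=5,
                             diffusivity_tau_frames=1)
        assert len(out) == 2
        for _, row in out.iterrows():
            se_cc = (row["sigma_parallel_um"] / np.sqrt(row["n_steps"])
                     / row["tau_s"] / row["mean_flow_speed_um_s"])
            assert row["cc"] == pytest.approx(1.0, abs=3 * se_cc)

    def test_empty_bin_flagged(self):
        cfg = cf.SimulationConfig(n_particles=100, D=0.05, k_off=0.0,
                                  duration=1.0, seed=22)
        traj, _ = cf.simulate_trajectories(cfg)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        with pytest.warns(UserWarning, match="too few"):
            out = cf.bin_and_fit(traj, flow, "intensity",
                                 bin_edges=[0.0, 1.0, 1000.0], tau_frames=5)
        assert np.isnan(out["cc"].iloc[0])  # nothing below intensity 1.0

    def test_bin_edge_order_irrelevant(self):
        cfg = cf.SimulationConfig(n_particles=200, D=0.05, k_off=0.0,
                                  v_parallel=0.1, duration=1.0, seed=23)
        traj, _ = cf.simulate_trajectories(cfg)
        flow = cf.FlowField.uniform(0.1, 0.0, extent=(300.0, 300.0), spacing=50.0)
        a = cf.bin_and_fit(traj, flow, "diffusivity", [0.0, 0.05, 0.5],
                           min_samples=50)
        b = cf.bin_and_fit(traj, flow, "diffusivity", [0.5, 0.0, 0.05],
                           min_samples=50)
        pd.testing.assert_frame_equal(a, b)


class TestDetectionPower:
    def test_tiny_diffusivity_always_detected(self):
        out = detection_power([0.001], v=0.1, n_replicates=20, seed=1)
        assert (out["p_value"] < 1e-6).all()

    def test_null_calibration_at_alpha(self):
        out = detection_power([0.1], v=0.0, n_replicates=400, seed=2)
        frac = out["significant"].mean()
        assert frac < 0.1  # ≈ alpha = 0.05 under the null

    def test_per_replicate_detection_boundary(self):
        # with single replicates of 1,000 displacements the detection
        # boundary sits near D ≈ 0.3 µm²/s: reliable well below, lost well above
        out = detection_power([0.05, 1.5], v=0.1, n_replicates=20, seed=3)
        low = out[out["D_um2_s"] == 0.05]["significant"].mean()
        high = out[out["D_um2_s"] == 1.5]["significant"].mean()
        assert low > 0.9
        assert high < 0.5

    def test_pooled_detection_limit_covers_reported_range(self):
        limit = detection_limit([0.001, 0.01, 0.1, 0.3, 1.0], v=0.1,
                                n_pooled=10, n_experiments=20, seed=4)
        assert limit >= 0.3
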