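"""Simulator: kinematic structure, noise bookkeeping, scenarios."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from rootkin.config import ConfigError, NoiseConfig, SimulationConfig
from rootkin.kinetics import KineticsConfig, add_coordinated_motility
from rootkin.simulate import (apply_scenario, render_frames, render_voxel_frame,
                              simulate_root)


def _truth_kin_table(truth):
    """Ground-truth cells relabelled as a kinematics-style table."""
    t = truth.cells.rename(columns={"nucleus_id": "track_id"}).copy()
    return t


class TestAdvection:
    def test_plateau_nucleus_moves_at_plateau_velocity(self):
        cfg = SimulationConfig(n_nuclei=1, division_rate=0.0, n_frames=9,
                               frame_interval_min=7.5)  # exactly 1 h span
        cfg.skew = dataclasses.replace(cfg.skew, omega=0.0)
        truth = simulate_root(cfg, initial_positions=[[0.0, 900.0, 0.0]])
        g = truth.cells.sort_values("frame")
        dy = g["y_um"].iloc[-1] - g["y_um"].iloc[0]
        assert dy == pytest.approx(cfg.axial_profile.v_plateau, rel=1e-6)
        assert np.allclose(g[["vx", "vz"]], 0.0)

    def test_axial_positions_match_ode_oracle(self, noiseless_config):
        # independent integration of dy/dt = v(y) for sampled nuclei
        truth = simulate_root(noiseless_config)
        profile = noiseless_config.axial_profile
        dt = noiseless_config.dt_h
        nf = noiseless_config.n_frames
        for nid in truth.cells["nucleus_id"].unique()[:8]:
            g = truth.cells[truth.cells["nucleus_id"] == nid].sort_values("frame")
            if g["y_um"].iloc[0] < noiseless_config.skew.meristem_extent:
                continue  # rotation-free check only
            sol = solve_ivp(lambda t, y: profile.velocity(y), (0, (nf - 1) * dt),
                            [g["y_um"].iloc[0]], t_eval=g["t_h"].to_numpy(),
                            rtol=1e-10, atol=1e-10)
            assert np.allclose(g["y_um"], sol.y[0], atol=1e-5)

    def test_elongation_zone_mean_velocity_near_plateau(self, noiseless_truth,
                                                        noiseless_config):
        ez = noiseless_truth.cells[noiseless_truth.cells["zone"] == "EZ"]
        assert ez["vy"].mean() == pytest.approx(
            noiseless_config.axial_profile.v_plateau, rel=0.02)

    def test_zone_velocity_monotone_up_to_plateau(self, noiseless_truth):
        cells = noiseless_truth.cells
        bins = pd.cut(cells["y_um"], np.arange(0, 1000, 100))
        mean_v = cells.groupby(bins, observed=True)["vy"].mean()
        assert (np.diff(mean_v.to_numpy()) > -1e-9).all()

    def test_velocity_equals_finite_difference_of_positions(self, noiseless_truth,
                                                            noiseless_config):
        dt = noiseless_config.dt_h
        for nid in noiseless_truth.cells["nucleus_id"].unique()[:10]:
            g = noiseless_truth.cells[noiseless_truth.cells["nucleus_id"] == nid]
            g = g.sort_values("frame")
            p = g[["x_um", "y_um", "z_um"]].to_numpy()
            v = g[["vx", "vy", "vz"]].to_numpy()
            fd = (p[2:] - p[:-2]) / (2 * dt)
            assert np.allclose(fd, v[1:-1], atol=0.5)


class TestSkewing:
    def test_opposite_flanks_have_antiparallel_lateral_velocities(self, skew_truth):
        mz = skew_truth.cells[(skew_truth.cells["frame"] == 0)
                              & (skew_truth.cells["zone"] == "MZ")]
        pos = mz[["x_um", "z_um"]].to_numpy()
        vel = mz[["vx", "vz"]].to_numpy()
        r = np.linalg.norm(pos, axis=1)
        ok = r > 10
        pos, vel = pos[ok], vel[ok]
        posu = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        velu = vel / np.linalg.norm(vel, axis=1, keepdims=True)
        opp = posu @ posu.T < -0.995  # nuclei on opposite flanks
        assert opp.any()
        cosv = velu @ velu.T
        assert np.all(cosv[opp] < -0.99)

    def test_lateral_velocity_position_correlation_negative_each_frame(self, skew_truth):
        # rigid rotation about +Y: vz = -omega_c * x, so corr(x, vz) = -1
        for _, g in skew_truth.cells.groupby("frame"):
            mz = g[g["zone"] == "MZ"]
            c = np.corrcoef(mz["x_um"], mz["vz"])[0, 1]
            assert c < -0.95

    def test_no_lateral_motion_without_skew(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config)
        cfg.skew = dataclasses.replace(cfg.skew, omega=0.0)
        truth = simulate_root(cfg)
        assert np.allclose(truth.cells[["vx", "vz"]], 0.0)

    def test_positions_stay_inside_root_cylinder(self, skew_truth):
        r = np.hypot(skew_truth.cells["x_um"], skew_truth.cells["z_um"])
        assert (r <= skew_truth.config.root_radius + 1e-6).all()


class TestDeterminismAndLineage:
    def test_identical_seed_gives_identical_truth(self, small_config):
        a = simulate_root(small_config)
        b = simulate_root(small_config)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_different_seed_differs(self, small_config):
        a = simulate_root(small_config)
        b = simulate_root(dataclasses.replace(small_config, seed=99))
        assert not a.cells[["x_um"]].equals(b.cells[["x_um"]])

    def test_division_children_appear_at_parent_position(self):
        cfg = SimulationConfig(seed=5, n_nuclei=200, n_frames=20, division_rate=0.5)
        truth = simulate_root(cfg)
        children = truth.cells[truth.cells["parent_id"] >= 0]
        assert len(children) > 0
        for cid in children["nucleus_id"].unique()[:10]:
            child = truth.cells[truth.cells["nucleus_id"] == cid].sort_values("frame")
            parent_id = child["parent_id"].iloc[0]
            parent = truth.cells[truth.cells["nucleus_id"] == parent_id].sort_values("frame")
            # parent's last frame immediately precedes the child's first
            assert parent["frame"].max() == child["frame"].min() - 1
            d = np.linalg.norm(
                child.iloc[0][["x_um", "y_um", "z_um"]].to_numpy(float)
                - parent.iloc[-1][["x_um", "y_um", "z_um"]].to_numpy(float))
            # 3 µm offset plus one frame of advection
            assert d < 3.0 + 15.0

    def test_invalid_config_rejected(self):
        cfg = SimulationConfig()
        cfg.axial_profile = dataclasses.replace(cfg.axial_profile, v_plateau=float("nan"))
        with pytest.raises(ConfigError):
            simulate_root(cfg)
        with pytest.raises(ConfigError):
            simulate_root(SimulationConfig(n_frames=1))


class TestRender:
    def test_noiseless_render_reproduces_positions_exactly(self, noiseless_truth):
        frames = render_frames(noiseless_truth)
        f0 = frames.frame(0).sort_values("true_id")
        t0 = noiseless_truth.cells[noiseless_truth.cells["frame"] == 0].sort_values("nucleus_id")
        assert np.array_equal(f0[["x_um", "y_um", "z_um"]].to_numpy(),
                              t0[["x_um", "y_um", "z_um"]].to_numpy())

    def test_dropout_count_within_binomial_interval(self):
        from scipy.stats import binom

        cfg = SimulationConfig(seed=21, n_nuclei=1000, n_frames=2, division_rate=0.0)
        cfg.noise = NoiseConfig(jitter_sd=0.0, dropout_rate=0.02)
        frames = render_frames(simulate_root(cfg))
        n_det = len(frames.frame(0))
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.98)
        assert lo <= n_det <= hi

    def test_mass_balance_bookkeeping(self, small_truth):
        cfg = dataclasses.replace(small_truth.config)
        cfg.noise = NoiseConfig(jitter_sd=0.5, dropout_rate=0.05, false_positive_rate=2.0)
        frames = render_frames(small_truth, cfg)
        bk = frames.bookkeeping
        assert (bk["n_detections"] == bk["n_true"] - bk["n_dropped"] + bk["n_fp"]).all()
        per_frame = frames.detections.groupby("frame").size()
        assert np.array_equal(per_frame.to_numpy(), bk["n_detections"].to_numpy())
        fp = frames.detections[frames.detections["true_id"] < 0].groupby("frame").size()
        assert fp.reindex(bk["frame"], fill_value=0).sum() == bk["n_fp"].sum()

    def test_default_density_covers_three_zones(self):
        truth = simulate_root(SimulationConfig(seed=3))
        f0 = truth.cells[truth.cells["frame"] == 0]
        assert len(f0) == 1000
        assert set(f0["zone"]) == {"MZ", "EZ", "DZ"}

    def test_voxel_render_too_small_grid_raises(self, noiseless_truth):
        with pytest.raises(ConfigError):
            render_voxel_frame(noiseless_truth, 0, shape=(4, 4, 4),
                               origin_um=(0.0, 0.0, 0.0))


class TestScenarios:
    def test_control_is_identity(self, small_truth):
        out = apply_scenario(small_truth, "control")
        pd.testing.assert_frame_equal(out.cells, small_truth.cells)

    def test_unknown_scenario_rejected(self, small_truth):
        with pytest.raises(ConfigError):
            apply_scenario(small_truth, "heat_shock")

    def test_induction_velocity_declines_after_peak(self):
        cfg = SimulationConfig(seed=31, n_nuclei=150, n_frames=40, division_rate=0.0)
        truth = simulate_root(cfg, scenario="auxin_induction",
                              scenario_params={"decay_rate_per_h": 0.5})
        ez = truth.cells[truth.cells["zone"] == "EZ"]
        v_early = ez[np.isclose(ez["t_h"], 0.4375)]["vy"].mean()  # 3 frames ~ 26 min
        v_late = ez[ez["frame"] == 39]["vy"].mean()
        assert v_late < v_early

    def test_skew_suppression_raises_meristem_coordination(self):
        cfg = SimulationConfig(seed=37, n_nuclei=250, n_frames=40, division_rate=0.0)
        truth = simulate_root(cfg, scenario="auxin_induction",
                              scenario_params={"skew_suppression": True})
        kin = _truth_kin_table(truth)
        kin = add_coordinated_motility(kin, KineticsConfig())
        mz = kin[kin["zone"] == "MZ"]
        cm_start = mz[mz["frame"] == 0]["cm"].mean()
        cm_end = mz[mz["frame"] == 39]["cm"].mean()
        assert cm_end > cm_start

    def test_reporter_flat_then_rising(self):
        cfg = SimulationConfig(seed=41, n_nuclei=100, n_frames=40, division_rate=0.0)
        truth = simulate_root(cfg)
        rep = truth.cells.groupby("frame")["reporter"].mean()
        delay = cfg.reporter.onset_delay_h
        dt = cfg.dt_h
        before = rep[rep.index * dt <= delay]
        assert np.allclose(before, before.iloc[0])
        assert rep.iloc[-1] > before.iloc[0]
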