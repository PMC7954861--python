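"""Kinematic quantities: velocities, angles, coordinated motility, features."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootkin.config import KineticsConfig
from rootkin.kinetics import (add_coordinated_motility, cell_feature_summary,
                              compute_kinematics, coordinated_motility,
                              feature_manifest, instantaneous_angle, msd_slope)


def track_table(positions, dt_h=0.1, track_id=0):
    p = np.asarray(positions, float)
    return pd.DataFrame({
        "track_id": track_id,
        "frame": np.arange(len(p)),
        "t_h": np.arange(len(p)) * dt_h,
        "x_um": p[:, 0], "y_um": p[:, 1], "z_um": p[:, 2],
        "gap_flag": False,
    })


class TestVelocities:
    def test_axial_displacement_gives_vy(self):
        t = track_table([[0, 0, 0], [0, 50, 0]], dt_h=1.0)
        kin = compute_kinematics(t, 60.0, KineticsConfig(differencing="forward"))
        assert kin["vy"].iloc[0] == pytest.approx(50.0)
        assert kin["speed"].iloc[0] == pytest.approx(50.0)

    def test_diagonal_path_speed_total_and_displacement(self):
        # step (3, 4, 0) µm per 0.1 h
        steps = np.array([[3.0 * k, 4.0 * k, 0.0] for k in range(5)])
        kin = compute_kinematics(track_table(steps), 6.0,
                                 KineticsConfig(differencing="forward"))
        assert kin["speed"].iloc[0] == pytest.approx(50.0)
        assert kin["velocity_total"].iloc[0] == pytest.approx(70.0)
        assert kin["disp2"].iloc[2] == pytest.approx(100.0)

    def test_constant_velocity_has_zero_acceleration(self):
        steps = np.array([[0.0, 5.0 * k, 0.0] for k in range(6)])
        kin = compute_kinematics(track_table(steps), 6.0)
        interior = kin["a_mag"].iloc[1:-2]
        assert np.allclose(interior.dropna(), 0.0, atol=1e-9)

    def test_central_differencing_boundary_samples_undefined(self):
        steps = np.array([[0.0, k, 0.0] for k in range(5)])
        kin = compute_kinematics(track_table(steps), 6.0)
        assert np.isnan(kin["vy"].iloc[0]) and np.isnan(kin["vy"].iloc[-1])
        assert np.isfinite(kin["vy"].iloc[1:-1]).all()

    def test_single_sample_track_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(track_table([[0, 0, 0]]), 6.0)

    def test_gap_samples_flagged(self):
        t = track_table([[0, 0, 0], [0, 1, 0], [0, 2, 0], [0, 3, 0]])
        t.loc[2, "gap_flag"] = True
        kin = compute_kinematics(t, 6.0)
        assert kin["from_gap"].iloc[1]  # central stencil touches the gap
        assert kin["from_gap"].iloc[2]


class TestInstantaneousAngle:
    @pytest.mark.parametrize("v,expected", [
        ((0, 1, 0), 0.0),
        ((1, 0, 0), 90.0),
        ((1, 1, 0), 45.0),
        ((0, -1, 0), 180.0),
    ])
    def test_reference_directions(self, v, expected):
        assert instantaneous_angle(np.array([v]))[0] == pytest.approx(expected)

    def test_zero_velocity_undefined(self):
        assert np.isnan(instantaneous_angle(np.array([[0.0, 0.0, 0.0]]))[0])


class TestCoordinatedMotility:
    def test_shared_direction_gives_unity(self):
        pos = np.random.default_rng(1).uniform(0, 50, size=(20, 3))
        vel = np.tile([1.0, 2.0, 0.5], (20, 1)) * np.linspace(0.5, 2, 20)[:, None]
        cm, n = coordinated_motility(pos, vel, 0)
        assert cm == pytest.approx(1.0)
        assert n == 19

    def test_single_antiparallel_neighbor(self):
        pos = np.array([[0, 0, 0], [10, 0, 0]])
        vel = np.array([[0, 1, 0], [0, -1, 0]])
        cm, _ = coordinated_motility(pos, vel, 0,
                                     KineticsConfig(cm_min_neighbors=1))
        assert cm == pytest.approx(-1.0)

    def test_parallel_plus_orthogonal_mean(self):
        pos = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        vel = np.array([[0, 1, 0], [0, 2, 0], [1, 0, 0]])
        cm, _ = coordinated_motility(pos, vel, 0,
                                     KineticsConfig(cm_min_neighbors=2))
        assert cm == pytest.approx(0.5)

    def test_zero_velocity_neighbor_excluded(self):
        pos = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        vel = np.array([[0, 1, 0], [0, 1, 0], [0, 0, 0]])
        cm, n = coordinated_motility(pos, vel, 0,
                                     KineticsConfig(cm_min_neighbors=1))
        assert cm == pytest.approx(1.0)
        assert n == 1

    def test_too_few_neighbors_undefined(self):
        pos = np.array([[0, 0, 0], [500, 0, 0]])
        vel = np.ones((2, 3))
        cm, n = coordinated_motility(pos, vel, 0)
        assert np.isnan(cm) and n == 0

    def test_isotropic_random_velocities_average_near_zero(self):
        rng = np.random.default_rng(7)
        n = 1001
        pos = rng.uniform(0, 50, size=(n, 3))
        vel = rng.normal(size=(n, 3))
        cm, n_nb = coordinated_motility(pos, vel, 0)
        assert n_nb == 1000
        assert abs(cm) < 3.0 / np.sqrt(n_nb)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_uniform_translation_gives_unity_for_every_center(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15)
        pos = rng.uniform(-100, 100, size=(n, 3))
        vel = np.tile(rng.normal(size=3) + 0.1, (n, 1))
        cfg = KineticsConfig(cm_radius=1000.0, cm_min_neighbors=1)
        for i in range(n):
            cm, _ = coordinated_motility(pos, vel, i, cfg)
            assert cm == pytest.approx(1.0)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, size=(30, 3))
        vel = rng.normal(size=(30, 3))
        R = Rotation.from_rotvec([0.3, 1.1, -0.4]).as_matrix()
        cfg = KineticsConfig(cm_min_neighbors=1)
        for i in (0, 5, 10):
            cm1, _ = coordinated_motility(pos, vel, i, cfg)
            cm2, _ = coordinated_motility(pos @ R.T, vel @ R.T, i, cfg)
            assert cm2 == pytest.approx(cm1)
        # speed and displacement² are rotation invariant too
        assert np.allclose(np.linalg.norm(vel @ R.T, axis=1),
                           np.linalg.norm(vel, axis=1))
        # the axial angle is invariant only under rotations about Y
        Ry = Rotation.from_rotvec([0, 0.8, 0]).as_matrix()
        assert np.allclose(instantaneous_angle(vel @ Ry.T), instantaneous_angle(vel))
        assert not np.allclose(instantaneous_angle(vel @ R.T), instantaneous_angle(vel))

    def test_add_cm_matches_single_center_computation(self):
        rng = np.random.default_rng(5)
        n = 25
        kin = pd.DataFrame({
            "track_id": np.arange(n), "frame": 0, "t_h": 0.0,
            "x_um": rng.uniform(0, 150, n), "y_um": rng.uniform(0, 150, n),
            "z_um": rng.uniform(0, 150, n),
            "vx": rng.normal(size=n), "vy": rng.normal(size=n), "vz": rng.normal(size=n),
        })
        out = add_coordinated_motility(kin)
        pos = kin[["x_um", "y_um", "z_um"]].to_numpy()
        vel = kin[["vx", "vy", "vz"]].to_numpy()
        for i in (0, 7, 19):
            cm, n_nb = coordinated_motility(pos, vel, i)
            assert out["cm"].iloc[i] == pytest.approx(cm, nan_ok=True)
            assert out["cm_n"].iloc[i] == n_nb


class TestFeatures:
    def test_manifest_has_at_least_36_features(self):
        manifest = feature_manifest()
        assert len(manifest) >= 36
        assert len({m["name"] for m in manifest}) == len(manifest)

    def test_feature_vector_matches_manifest(self):
        steps = np.array([[0.0, 5.0 * k, 0.0] for k in range(12)])
        kin = compute_kinematics(track_table(steps), 6.0)
        kin = add_coordinated_motility(kin)
        feats = cell_feature_summary(kin, 6.0)
        names = {m["name"] for m in feature_manifest()}
        assert names == set(feats.columns)

    def test_ballistic_track_directionality_and_msd(self):
        steps = np.array([[1.5 * k, 2.0 * k, 0.0] for k in range(40)])
        kin = compute_kinematics(track_table(steps), 6.0)
        feats = cell_feature_summary(kin, 6.0)
        assert feats["directionality_ratio"].iloc[0] == pytest.approx(1.0)
        assert feats["msd_slope"].iloc[0] == pytest.approx(2.0, abs=0.05)

    def test_random_walk_msd_slope_near_one(self):
        rng = np.random.default_rng(11)
        # average the slope estimate over several independent walks
        slopes = []
        for _ in range(20):
            steps = np.cumsum(rng.normal(size=(400, 3)), axis=0)
            slopes.append(msd_slope(np.arange(400) * 0.1, steps))
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)

    def test_stationary_track_features(self):
        steps = np.zeros((10, 3))
        kin = compute_kinematics(track_table(steps), 6.0)
        feats = cell_feature_summary(kin, 6.0)
        assert feats["speed_mean"].iloc[0] == 0.0
        assert feats["vy_max"].iloc[0] == 0.0
        assert np.isnan(feats["directionality_ratio"].iloc[0])
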