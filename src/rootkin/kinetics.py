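"""Per-cell morphokinetic quantities.

From a track table (one row per track and frame, µm positions) this module
derives velocity components, Euclidean speed, velocity-total (the sum of
the per-axis velocity magnitudes, reported alongside speed because lateral
skewing contributes to it even when axial speed dominates), acceleration,
displacement-squared from the track origin, the instantaneous angle to the
root axis, and coordinated motility — the mean cosine between a center
cell's velocity and the velocities of all cells within a fixed radius
(200 µm by default).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import KineticsConfig

__all__ = [
    "compute_kinematics",
    "instantaneous_angle",
    "coordinated_motility",
    "add_coordinated_motility",
    "cell_feature_summary",
    "feature_manifest",
    "msd_slope",
]


def instantaneous_angle(v: np.ndarray) -> np.ndarray:
    """Angle (degrees, [0, 180]) between velocity and the +Y root axis.

    NaN where the velocity is zero or undefined.
    """
    v = np.atleast_2d(np.asarray(v, float))
    norm = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norm > 0, v[:, 1] / norm, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _diff_velocity(t: np.ndarray, p: np.ndarray, scheme: str) -> np.ndarray:
    v = np.full_like(p, np.nan)
    if scheme == "central":
        v[1:-1] = (p[2:] - p[:-2]) / (t[2:] - t[:-2])[:, None]
    else:  # forward
        v[:-1] = (p[1:] - p[:-1]) / (t[1:] - t[:-1])[:, None]
    return v


def compute_kinematics(tracks: pd.DataFrame, frame_interval_min: float,
                       config: KineticsConfig | None = None) -> pd.DataFrame:
    """Per-sample kinematics for every track in a track table.

    Velocities use the configured finite-difference scheme on the (gap-
    interpolated) positions; boundary samples where the stencil is
    undefined carry NaN. Acceleration is the forward difference of
    successive velocities. ``from_gap`` flags samples whose velocity
    stencil touched an interpolated gap row. Tracks must have >= 2 samples.
    """
    config = config or KineticsConfig()
    config.validate()
    if tracks.groupby("track_id").size().min() < 2:
        raise ValueError("every track needs at least 2 samples")
    out = []
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        t = g["t_h"].to_numpy()
        p = g[["x_um", "y_um", "z_um"]].to_numpy()
        gapf = g["gap_flag"].to_numpy() if "gap_flag" in g else np.zeros(len(g), bool)
        v = _diff_velocity(t, p, config.differencing)
        a = np.full_like(v, np.nan)
        a[:-1] = (v[1:] - v[:-1]) / (t[1:] - t[:-1])[:, None]
        disp2 = np.sum((p - p[0]) ** 2, axis=1)
        # a velocity sample is gap-derived if any position in its stencil is
        if config.differencing == "central":
            from_gap = np.zeros(len(g), bool)
            from_gap[1:-1] = gapf[2:] | gapf[:-2] | gapf[1:-1]
        else:
            from_gap = gapf.copy()
            from_gap[:-1] |= gapf[1:]
        speed = np.linalg.norm(v, axis=1)
        kin = pd.DataFrame({
            "track_id": tid,
            "frame": g["frame"].to_numpy(),
            "t_h": t,
            "x_um": p[:, 0], "y_um": p[:, 1], "z_um": p[:, 2],
            "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2],
            "speed": speed,
            "velocity_total": np.abs(v).sum(axis=1),
            "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
            "a_mag": np.linalg.norm(a, axis=1),
            "disp2": disp2,
            "angle_deg": instantaneous_angle(v),
            "gap_flag": gapf,
            "from_gap": from_gap,
        })
        out.append(kin)
    table = pd.concat(out, ignore_index=True)
    for c in tracks.columns:
        if c.startswith("ch_") or c == "true_id":
            table[c] = tracks.sort_values(["track_id", "frame"])[c].to_numpy()
    return table


def coordinated_motility(positions: np.ndarray, velocities: np.ndarray,
                         center_index: int, config: KineticsConfig | None = None):
    """Coordinated motility of one center cell within a single frame.

    CM = mean over neighbours j (cells within ``cm_radius`` of the center,
    excluding it) of cos(angle(v_center, v_j)). Neighbours with zero or
    undefined velocity are excluded from the mean but reported in the
    count. Returns (cm, n_neighbors_used); cm is NaN when fewer than
    ``cm_min_neighbors`` usable neighbours exist or the center velocity is
    undefined.
    """
    config = config or KineticsConfig()
    positions = np.asarray(positions, float)
    velocities = np.asarray(velocities, float)
    vc = velocities[center_index]
    nc = np.linalg.norm(vc)
    if not np.isfinite(nc) or nc == 0:
        return np.nan, 0
    d = np.linalg.norm(positions - positions[center_index], axis=1)
    nb = (d <= config.cm_radius) & (np.arange(len(positions)) != center_index)
    vn = velocities[nb]
    norms = np.linalg.norm(vn, axis=1)
    ok = np.isfinite(norms) & (norms > 0)
    if ok.sum() < config.cm_min_neighbors:
        return np.nan, int(ok.sum())
    cos = (vn[ok] @ (vc / nc)) / norms[ok]
    return float(cos.mean()), int(ok.sum())


def add_coordinated_motility(kin: pd.DataFrame,
                             config: KineticsConfig | None = None) -> pd.DataFrame:
    """Append per-sample CM columns ('cm', 'cm_n') to a kinematics table.

    Every cell acts in turn as the center within its frame; neighbourhoods
    use 3D distances between same-frame positions.
    """
    config = config or KineticsConfig()
    kin = kin.copy()
    cm = np.full(len(kin), np.nan)
    cm_n = np.zeros(len(kin), int)
    for _, g in kin.groupby("frame"):
        idx = g.index.to_numpy()
        pos = g[["x_um", "y_um", "z_um"]].to_numpy()
        vel = g[["vx", "vy", "vz"]].to_numpy()
        norms = np.linalg.norm(vel, axis=1)
        ok = np.isfinite(norms) & (norms > 0)
        if ok.sum() == 0:
            continue
        tree = cKDTree(pos)
        unit = np.zeros_like(vel)
        unit[ok] = vel[ok] / norms[ok, None]
        neighbor_lists = tree.query_ball_point(pos, config.cm_radius)
        for local_i, nbrs in enumerate(neighbor_lists):
            if not ok[local_i]:
                continue
            nbrs = [j for j in nbrs if j != local_i and ok[j]]
            if len(nbrs) < config.cm_min_neighbors:
                cm_n[idx[local_i]] = len(nbrs)
                continue
            cm[idx[local_i]] = float(np.mean(unit[nbrs] @ unit[local_i]))
            cm_n[idx[local_i]] = len(nbrs)
    kin["cm"] = cm
    kin["cm_n"] = cm_n
    return kin


def msd_slope(t: np.ndarray, p: np.ndarray, max_lag_fraction: float = 0.25):
    """Log-log slope of the mean-squared displacement over short lags.

    Slope 2 indicates ballistic motion, 1 diffusive. Uses lags up to a
    quarter of the track length (at least 2 lags). NaN for degenerate
    (stationary) tracks.
    """
    n = len(t)
    max_lag = max(2, int(n * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean(np.sum((p[lag:] - p[:-lag]) ** 2, axis=1)) for lag in lags])
    dt = np.median(np.diff(t))
    if np.any(msd <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(lags * dt), np.log(msd), 1)
    return float(slope)


_BASE_STATS = ("mean", "sd", "max")
_BASE_QUANTITIES = ("vx", "vy", "vz", "speed", "velocity_total", "a_mag",
                    "angle_deg", "cm", "disp2", "lateral_speed")


def feature_manifest() -> list[dict]:
    """Machine-readable list of the per-cell morphokinetic features."""
    manifest = []
    units = {"vx": "µm/h", "vy": "µm/h", "vz": "µm/h", "speed": "µm/h",
             "velocity_total": "µm/h", "a_mag": "µm/h²", "angle_deg": "deg",
             "cm": "unitless", "disp2": "µm²", "lateral_speed": "µm/h"}
    for q in _BASE_QUANTITIES:
        for s in _BASE_STATS:
            manifest.append({"name": f"{q}_{s}", "units": units[q],
                             "formula": f"{s} over time of {q}"})
    manifest += [
        {"name": "duration_s", "units": "s", "formula": "frame span × Δt"},
        {"name": "net_displacement", "units": "µm", "formula": "‖p(T) − p(0)‖"},
        {"name": "path_length", "units": "µm", "formula": "Σ ‖Δp‖"},
        {"name": "directionality_ratio", "units": "unitless", "formula": "net / path"},
        {"name": "msd_slope", "units": "unitless", "formula": "log–log MSD fit, first-quarter lags"},
        {"name": "eccentricity_mean", "units": "unitless", "formula": "mean nuclear eccentricity"},
        {"name": "area_mean", "units": "µm²", "formula": "mean projected nuclear area"},
    ]
    return manifest


def cell_feature_summary(kin: pd.DataFrame, frame_interval_min: float,
                         morphology: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-track morphokinetic feature vectors (37 features).

    {mean, sd, max} over time of each kinematic quantity, plus duration,
    net displacement, path length, directionality ratio and the MSD
    log-log slope; nuclear eccentricity / projected area means are taken
    from ``morphology`` (indexed by track_id) when given, NaN otherwise.
    Samples flagged ``from_gap`` are excluded from the time statistics.
    """
    rows = []
    for tid, g in kin.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        use = g[~g["from_gap"]] if "from_gap" in g else g
        if use[["vx", "vy", "vz"]].notna().any(axis=1).sum() == 0:
            # rare tracks where every stencil touches a bridged gap: fall
            # back to the gap-derived samples rather than dropping the cell
            use = g
        if use[["vx", "vy", "vz"]].notna().any(axis=1).sum() == 0:
            raise ValueError(f"track {tid} has no defined kinematic samples")
        feat = {"track_id": tid}
        lateral = np.sqrt(use["vx"] ** 2 + use["vz"] ** 2)
        quantities = {q: use[q] if q in use else pd.Series(dtype=float)
                      for q in _BASE_QUANTITIES if q != "lateral_speed"}
        quantities["lateral_speed"] = lateral
        for q, series in quantities.items():
            vals = series.to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                feat[f"{q}_mean"] = feat[f"{q}_sd"] = feat[f"{q}_max"] = np.nan
            else:
                feat[f"{q}_mean"] = float(vals.mean())
                feat[f"{q}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                feat[f"{q}_max"] = float(vals.max())
        p = g[["x_um", "y_um", "z_um"]].to_numpy()
        t = g["t_h"].to_numpy()
        feat["duration_s"] = float((g["frame"].max() - g["frame"].min()) * frame_interval_min * 60.0)
        net = float(np.linalg.norm(p[-1] - p[0]))
        path = float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
        feat["net_displacement"] = net
        feat["path_length"] = path
        feat["directionality_ratio"] = net / path if path > 0 else np.nan
        feat["msd_slope"] = msd_slope(t, p) if len(p) >= 8 else np.nan
        feat["eccentricity_mean"] = np.nan
        feat["area_mean"] = np.nan
        rows.append(feat)
    table = pd.DataFrame(rows).set_index("track_id")
    if morphology is not None:
        for col, target in (("eccentricity", "eccentricity_mean"), ("area_um2", "area_mean")):
            if col in morphology:
                table[target] = morphology.groupby("track_id")[col].mean().reindex(table.index)
    return table
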