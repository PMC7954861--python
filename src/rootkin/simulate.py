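"""Synthetic root-growth simulator.

Generates ground-truth nucleus trajectories with the kinematic structure of
a growing Arabidopsis-style root imaged in 4D: a sigmoidal axial velocity
field that plateaus in the elongation zone, rigid rotational skewing of the
meristem (opposing lateral motion on opposite flanks of the root diameter),
Poisson cell division in the meristem, and a delayed auxin-response
reporter. A rendering step emulates acquisition: detection jitter, dropouts,
false positives, channel intensities, and (optionally) voxel stacks.

Coordinates are right-handed µm with the root axis along +Y, tip at y = 0
in the tip frame, shootward positive. Times are hours internally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .config import ConfigError, ReporterConfig, SimulationConfig

__all__ = [
    "GroundTruth",
    "FrameSet",
    "simulate_root",
    "apply_scenario",
    "render_frames",
    "render_voxel_frame",
    "write_voxel_movie",
    "read_voxel_movie",
    "zone_label",
    "SCENARIOS",
]

ZONE_ORDER = ("MZ", "EZ", "DZ")

TRUTH_COLUMNS = [
    "nucleus_id", "parent_id", "frame", "t_h",
    "x_um", "y_um", "z_um", "vx", "vy", "vz", "zone", "reporter",
]


def zone_label(y_from_tip, meristem_end: float, elongation_end: float):
    """Developmental zone from axial distance to the tip (half-open bins)."""
    y = np.asarray(y_from_tip, float)
    out = np.where(y < meristem_end, "MZ", np.where(y < elongation_end, "EZ", "DZ"))
    return out


@dataclass
class GroundTruth:
    """Simulated per-nucleus trajectories with lineage and reporter levels.

    ``cells`` has one row per (nucleus, frame) with true tip-frame positions
    (µm), true velocities (µm/h), zone labels and reporter intensity;
    ``tip`` gives the tip position per frame so lab-frame coordinates can be
    reconstructed. ``auxin_level`` is the scenario's phenomenological auxin
    signal per frame (0 for control), used by the ratiometric reporter.
    """

    cells: pd.DataFrame
    tip: pd.DataFrame
    config: SimulationConfig
    scenario: str = "control"
    auxin_level: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.auxin_level is None:
            self.auxin_level = np.zeros(self.config.n_frames)

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: SimulationConfig) -> "GroundTruth":
        cells = pd.read_csv(path)
        tip = _tip_frame(config)
        return cls(cells=cells, tip=tip, config=config)


@dataclass
class FrameSet:
    """Per-frame detected nuclei plus imaging geometry.

    ``detections``: one row per detection with noisy centroid, channel mean
    intensities and (for simulated data) the true nucleus id, -1 for
    spurious detections. ``bookkeeping`` records per frame the exact
    counts: true nuclei, dropouts, false positives, detections.
    """

    detections: pd.DataFrame
    frame_interval_min: float
    channels: tuple[str, ...] = ("nuclei", "reporter", "dii", "mdii")
    voxel_size_um: tuple[float, float, float] | None = None
    bookkeeping: pd.DataFrame | None = None

    @property
    def dt_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        return int(self.detections["frame"].max()) + 1 if len(self.detections) else 0

    def frame(self, i: int) -> pd.DataFrame:
        return self.detections[self.detections["frame"] == i]

    def to_csv(self, path) -> None:
        self.detections.to_csv(path, index=False)


def _tip_frame(config: SimulationConfig) -> pd.DataFrame:
    # The acquisition follows the tip (tip-tracking stage), so the tip is
    # stationary in the imaged field of view.
    frames = np.arange(config.n_frames)
    tx, ty, tz = config.tip_position
    return pd.DataFrame({
        "frame": frames,
        "t_h": frames * config.dt_h,
        "tip_x": tx, "tip_y": ty, "tip_z": tz,
    })


def _reporter_intensity(y: np.ndarray, t: float, rep: ReporterConfig, scale: float = 1.0) -> np.ndarray:
    if t <= rep.onset_delay_h:
        g = 0.0
    else:
        g = 1.0 - math.exp(-(t - rep.onset_delay_h) / max(rep.rise_time_h, 1e-9))
    spatial = np.exp(-0.5 * ((y - rep.spatial_origin_um) / rep.spatial_width_um) ** 2)
    return rep.baseline + scale * rep.amplitude * g * spatial


# ---------------------------------------------------------------------------
# scenarios


def _induction_profiles(t_peak_h=0.5, boost=0.3, decay_rate_per_h=0.5,
                        skew_suppression=False, skew_tau_h=1.0, dose=1.0,
                        auxin_tau_h=2.0):
    """Velocity / skew / auxin time profiles for an auxin-induction scenario.

    Axial velocities ramp up by ``boost`` towards a peak at ``t_peak_h``
    then decline exponentially at ``decay_rate_per_h`` (velocity rises in
    the first half hour after induction, then steeply declines). With
    ``skew_suppression`` the meristem rotation rate decays to zero.
    """
    b = boost * dose

    def vel_mod(t: float) -> float:
        if t <= t_peak_h:
            return 1.0 + b * t / t_peak_h
        return (1.0 + b) * math.exp(-decay_rate_per_h * (t - t_peak_h))

    def omega_mod(t: float) -> float:
        if not skew_suppression:
            return 1.0
        return math.exp(-t / skew_tau_h)

    def auxin(t: float) -> float:
        return dose * (1.0 - math.exp(-t / auxin_tau_h))

    return vel_mod, omega_mod, auxin


SCENARIOS = ("control", "auxin_induction", "exogenous_IAA")


def _scenario_profiles(name: str, params: dict):
    if name == "control":
        return None, None, None, 1.0
    if name == "auxin_induction":
        p = dict(t_peak_h=0.5, boost=0.3, decay_rate_per_h=0.5,
                 skew_suppression=False, skew_tau_h=1.0, dose=1.0)
        p.update(params)
        vel, om, aux = _induction_profiles(**p)
        return vel, om, aux, p["dose"]
    if name == "exogenous_IAA":
        dose = params.get("dose", 1.0)
        vel, om, aux = _induction_profiles(
            t_peak_h=params.get("t_peak_h", 0.5), boost=0.3 * dose,
            decay_rate_per_h=params.get("decay_rate_per_h", 0.5) * dose,
            skew_suppression=params.get("skew_suppression", dose >= 1.0),
            dose=dose)
        return vel, om, aux, dose
    raise ConfigError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# core integrator


def simulate_root(config: SimulationConfig, *, scenario: str | None = None,
                  scenario_params: dict | None = None, substeps: int = 6,
                  initial_positions: np.ndarray | None = None) -> GroundTruth:
    """Simulate ground-truth nucleus trajectories for one root.

    Nuclei are seeded uniformly in a cylinder of the configured radius over
    [0, root_length] from the tip, advected by the sigmoidal axial velocity
    field, twisted rigidly within the meristem, and divided as a Poisson
    process. Deterministic for a fixed seed. Scenario profiles (if any)
    modulate axial velocity and skew rate over time and set the auxin level
    driving the ratiometric reporter. ``initial_positions`` (n, 3) replaces
    the random seeding, for controlled experiments.
    """
    config.validate()
    scenario = scenario if scenario is not None else config.scenario
    vel_mod, omega_mod, auxin_fn, dose = _scenario_profiles(scenario, scenario_params or {})

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    if initial_positions is not None:
        initial_positions = np.atleast_2d(np.asarray(initial_positions, float))
        n = len(initial_positions)
        x = initial_positions[:, 0].copy()
        y = initial_positions[:, 1].copy()
        z = initial_positions[:, 2].copy()
    else:
        n = config.n_nuclei
        # uniform in the cylinder cross-section
        r = config.root_radius * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        x = r * np.cos(phi)
        z = r * np.sin(phi)
        y = rng.uniform(0.0, config.root_length, size=n)

    dt_h = config.dt_h
    sub_dt = dt_h / substeps
    tau = math.radians(config.skew.axis_tilt_deg)
    profile = config.axial_profile
    mz_end, ez_end = config.zones
    div_p = 1.0 - math.exp(-config.division_rate * dt_h) if config.division_rate > 0 else 0.0

    ids = np.arange(n, dtype=int)
    parents = np.full(n, -1, dtype=int)
    next_id = n
    alive = np.ones(n, dtype=bool)

    rows_id, rows_parent, rows_frame = [], [], []
    rows_x, rows_y, rows_z = [], [], []
    rows_vx, rows_vy, rows_vz = [], [], []
    auxin_level = np.zeros(config.n_frames)

    def velocities(xa, ya, za, t):
        m = vel_mod(t) if vel_mod is not None else 1.0
        om = config.skew.omega * (omega_mod(t) if omega_mod is not None else 1.0)
        vy = m * profile.velocity(ya)
        vx = np.zeros_like(xa)
        vz = np.zeros_like(za)
        mer = ya < config.skew.meristem_extent
        if om > 0 and mer.any():
            oc, os_ = om * math.cos(tau), om * math.sin(tau)
            vx[mer] = oc * za[mer]
            vz[mer] = -oc * xa[mer]
            vy = vy + np.where(mer, -os_ * za, 0.0)
        return vx, vy, vz

    def record(frame, t):
        vx, vy, vz = velocities(x[alive], y[alive], z[alive], t)
        rows_id.append(ids[alive].copy())
        rows_parent.append(parents[alive].copy())
        rows_frame.append(np.full(alive.sum(), frame))
        rows_x.append(x[alive].copy()); rows_y.append(y[alive].copy()); rows_z.append(z[alive].copy())
        rows_vx.append(vx); rows_vy.append(vy); rows_vz.append(vz)

    for frame in range(config.n_frames):
        t = frame * dt_h
        auxin_level[frame] = auxin_fn(t) if auxin_fn is not None else 0.0
        record(frame, t)
        if frame == config.n_frames - 1:
            break
        # advance to the next frame
        for s in range(substeps):
            ts = t + s * sub_dt
            m = vel_mod(ts + 0.5 * sub_dt) if vel_mod is not None else 1.0
            om = config.skew.omega * (omega_mod(ts + 0.5 * sub_dt) if omega_mod is not None else 1.0)
            ya, xa, za = y[alive], x[alive], z[alive]
            mer = ya < config.skew.meristem_extent
            # RK4 on the axial ODE dy/dt = m*v(y) (lateral shear added below)
            k1 = m * profile.velocity(ya)
            k2 = m * profile.velocity(ya + 0.5 * sub_dt * k1)
            k3 = m * profile.velocity(ya + 0.5 * sub_dt * k2)
            k4 = m * profile.velocity(ya + sub_dt * k3)
            dy = sub_dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if om > 0 and mer.any():
                oc, os_ = om * math.cos(tau), om * math.sin(tau)
                dy = dy + np.where(mer, -os_ * za * sub_dt, 0.0)
                theta = oc * sub_dt
                ct, st = math.cos(theta), math.sin(theta)
                xr = xa[mer] * ct + za[mer] * st
                zr = -xa[mer] * st + za[mer] * ct
                xa = xa.copy(); za = za.copy()
                xa[mer] = xr; za[mer] = zr
                x[alive] = xa; z[alive] = za
            y[alive] = ya + dy
        # divisions at the end of the interval: parent's last frame is
        # `frame`, the two children first appear at frame+1 at the parent's
        # position +/- a 3 µm offset
        if div_p > 0:
            mer_alive = alive & (y < config.skew.meristem_extent)
            cand = np.where(mer_alive)[0]
            if len(cand):
                divide = cand[rng.uniform(size=len(cand)) < div_p]
                for idx in divide:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    offset = 3.0 * direction
                    for sign in (+1.0, -1.0):
                        px = x[idx] + sign * offset[0]
                        py = max(y[idx] + sign * offset[1], 0.0)
                        pz = z[idx] + sign * offset[2]
                        rad = math.hypot(px, pz)
                        if rad > config.root_radius:  # keep children inside the root
                            scale = config.root_radius / rad
                            px *= scale; pz *= scale
                        ids = np.append(ids, next_id)
                        parents = np.append(parents, ids[idx])
                        x = np.append(x, px); y = np.append(y, py); z = np.append(z, pz)
                        alive = np.append(alive, True)
                        next_id += 1
                    alive[idx] = False

    cells = pd.DataFrame({
        "nucleus_id": np.concatenate(rows_id),
        "parent_id": np.concatenate(rows_parent),
        "frame": np.concatenate(rows_frame),
        "x_um": np.concatenate(rows_x),
        "y_um": np.concatenate(rows_y),
        "z_um": np.concatenate(rows_z),
        "vx": np.concatenate(rows_vx),
        "vy": np.concatenate(rows_vy),
        "vz": np.concatenate(rows_vz),
    })
    cells["t_h"] = cells["frame"] * dt_h
    cells["zone"] = zone_label(cells["y_um"], mz_end, ez_end)
    rep_scale = dose if scenario != "control" else 1.0
    reporter = np.empty(len(cells))
    for frame, grp in cells.groupby("frame"):
        reporter[grp.index] = _reporter_intensity(
            grp["y_um"].to_numpy(), frame * dt_h, config.reporter, rep_scale)
    cells["reporter"] = reporter
    cells = cells[TRUTH_COLUMNS].sort_values(["frame", "nucleus_id"]).reset_index(drop=True)

    cfg = replace(config, scenario=scenario)
    return GroundTruth(cells=cells, tip=_tip_frame(config), config=cfg,
                       scenario=scenario, auxin_level=auxin_level)


def apply_scenario(truth: GroundTruth, scenario: str, **params) -> GroundTruth:
    """Re-simulate the root under a kinetic scenario.

    ``control`` returns the input unchanged. Induction scenarios modulate
    the axial velocity with a rise-then-exponential-decline time profile,
    optionally suppress meristem skewing, and drive the auxin level used by
    the ratiometric reporter channels.
    """
    if scenario == "control":
        return truth
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    return simulate_root(truth.config, scenario=scenario, scenario_params=params)


# ---------------------------------------------------------------------------
# rendering


def render_frames(truth: GroundTruth, config: SimulationConfig | None = None) -> FrameSet:
    """Emulate acquisition on ground truth, producing a point-mode FrameSet.

    True positions are perturbed by isotropic Gaussian jitter, dropped
    independently with the configured dropout rate, and spurious detections
    are added at the configured Poisson rate. Channel intensities: 'nuclei'
    (constant marker), 'reporter' (delayed DR5-like signal), 'dii'/'mdii'
    (ratiometric pair; auxin degrades the dii channel only), all with
    additive Gaussian noise.
    """
    config = config or truth.config
    noise = config.noise
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 29]))
    dt_h = config.dt_h

    out = []
    book = []
    for frame in range(truth.n_frames):
        cells = truth.cells[truth.cells["frame"] == frame]
        n_true = len(cells)
        keep = rng.uniform(size=n_true) >= noise.dropout_rate
        n_drop = int(n_true - keep.sum())
        kept = cells[keep]
        pos = kept[["x_um", "y_um", "z_um"]].to_numpy()
        if noise.jitter_sd > 0:
            pos = pos + rng.normal(scale=noise.jitter_sd, size=pos.shape)
        n_fp = int(rng.poisson(noise.false_positive_rate))
        if n_fp:
            r = config.root_radius * np.sqrt(rng.uniform(size=n_fp))
            phi = rng.uniform(0, 2 * np.pi, size=n_fp)
            fp_pos = np.column_stack([
                r * np.cos(phi),
                rng.uniform(0, config.root_length, size=n_fp),
                r * np.sin(phi),
            ])
            pos = np.vstack([pos, fp_pos])
        n_det = len(pos)
        aux = float(truth.auxin_level[frame])
        frame_df = pd.DataFrame({
            "frame": frame,
            "t_h": frame * dt_h,
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "true_id": np.concatenate([kept["nucleus_id"].to_numpy(),
                                       np.full(n_fp, -1, dtype=int)]),
        })
        sd = noise.intensity_noise_sd
        rep_true = np.concatenate([kept["reporter"].to_numpy(),
                                   np.full(n_fp, config.reporter.baseline)])
        frame_df["ch_nuclei"] = np.clip(100.0 + rng.normal(scale=sd, size=n_det), 0, None)
        frame_df["ch_reporter"] = np.clip(rep_true + rng.normal(scale=sd, size=n_det), 0, None)
        frame_df["ch_mdii"] = np.clip(100.0 + rng.normal(scale=sd, size=n_det), 0, None)
        frame_df["ch_dii"] = np.clip(100.0 * math.exp(-aux) + rng.normal(scale=sd, size=n_det), 0, None)
        out.append(frame_df)
        book.append((frame, n_true, n_drop, n_fp, n_det))

    detections = pd.concat(out, ignore_index=True)
    bookkeeping = pd.DataFrame(book, columns=["frame", "n_true", "n_dropped", "n_fp", "n_detections"])
    return FrameSet(detections=detections, frame_interval_min=config.frame_interval_min,
                    bookkeeping=bookkeeping)


def render_voxel_frame(truth: GroundTruth, frame: int,
                       voxel_size_um: tuple[float, float, float] = (1.4, 1.0, 1.0),
                       origin_um: tuple[float, float, float] | None = None,
                       shape: tuple[int, int, int] | None = None,
                       blob_sigma_um: float = 2.5,
                       peak: float = 100.0,
                       channel: str = "nuclei") -> tuple[np.ndarray, tuple[float, float, float]]:
    """Paint one frame's nuclei as 3D Gaussian blobs into a ZYX voxel grid.

    ``voxel_size_um`` is (z, y, x). The grid must cover the root extent;
    a grid too small for the rendered nuclei raises ``ConfigError``.
    Returns the stack and the world (x, y, z) origin of voxel (0, 0, 0).
    Intended for small test volumes and for exercising the detection stage;
    write with ``tifffile.imwrite(path, stack)`` for ImageJ-style output.
    """
    cells = truth.cells[truth.cells["frame"] == frame]
    pos = cells[["x_um", "y_um", "z_um"]].to_numpy()
    amp = np.full(len(cells), peak)
    if channel == "reporter":
        amp = cells["reporter"].to_numpy()
    vz, vy, vx = voxel_size_um
    if origin_um is None:
        origin_um = (pos[:, 0].min() - 4 * blob_sigma_um,
                     pos[:, 1].min() - 4 * blob_sigma_um,
                     pos[:, 2].min() - 4 * blob_sigma_um)
    ox, oy, oz = origin_um
    if shape is None:
        shape = (int(np.ceil((pos[:, 2].max() - oz + 4 * blob_sigma_um) / vz)) + 1,
                 int(np.ceil((pos[:, 1].max() - oy + 4 * blob_sigma_um) / vy)) + 1,
                 int(np.ceil((pos[:, 0].max() - ox + 4 * blob_sigma_um) / vx)) + 1)
    nz, ny, nx = shape
    extent = (oz + nz * vz, oy + ny * vy, ox + nx * vx)
    if (pos[:, 2].max() > extent[0] or pos[:, 1].max() > extent[1]
            or pos[:, 0].max() > extent[2]):
        raise ConfigError("voxel grid too small for the simulated root extent")
    stack = np.zeros(shape, dtype=np.float32)
    zc = np.arange(nz) * vz + oz
    yc = np.arange(ny) * vy + oy
    xc = np.arange(nx) * vx + ox
    for (px, py, pz), a in zip(pos, amp):
        gz = np.exp(-0.5 * ((zc - pz) / blob_sigma_um) ** 2)
        gy = np.exp(-0.5 * ((yc - py) / blob_sigma_um) ** 2)
        gx = np.exp(-0.5 * ((xc - px) / blob_sigma_um) ** 2)
        stack += a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return stack, (ox, oy, oz)


def write_voxel_movie(truth: GroundTruth, path,
                      voxel_size_um: tuple[float, float, float] = (1.4, 1.0, 1.0),
                      channel: str = "nuclei", blob_sigma_um: float = 2.5,
                      margin_um: float = 10.0):
    """Render every frame onto a common grid and write a TZYX ImageJ TIFF.

    All frames share one voxel grid covering the whole movie (plus
    ``margin_um``), so the result is a standard 16-bit multi-page stack.
    Returns the grid origin in world (x, y, z) µm.
    """
    import tifffile

    cells = truth.cells
    lo = cells[["x_um", "y_um", "z_um"]].min().to_numpy() - margin_um
    hi = cells[["x_um", "y_um", "z_um"]].max().to_numpy() + margin_um
    vz, vy, vx = voxel_size_um
    shape = (int(np.ceil((hi[2] - lo[2]) / vz)) + 1,
             int(np.ceil((hi[1] - lo[1]) / vy)) + 1,
             int(np.ceil((hi[0] - lo[0]) / vx)) + 1)
    origin = tuple(lo)
    frames = []
    for f in range(truth.n_frames):
        stack, _ = render_voxel_frame(truth, f, voxel_size_um=voxel_size_um,
                                      origin_um=origin, shape=shape,
                                      blob_sigma_um=blob_sigma_um, channel=channel)
        frames.append(stack)
    movie = np.stack(frames)  # TZYX
    scale = 65535.0 / max(movie.max(), 1e-9)
    tifffile.imwrite(path, (movie * min(scale, 1.0) if scale < 1.0 else movie)
                     .astype(np.uint16), imagej=True,
                     metadata={"axes": "TZYX"})
    return origin


def read_voxel_movie(path) -> np.ndarray:
    """Read a TZYX multi-page TIFF movie as written by write_voxel_movie."""
    import tifffile

    movie = tifffile.imread(path)
    if movie.ndim == 3:
        movie = movie[None]
    return movie
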