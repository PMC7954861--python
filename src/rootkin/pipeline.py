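"""Pipeline orchestration: simulate → render → track → kinetics → maps →
reporters → cohort, with TOML config, run manifests and I/O validation.

Point-mode runs (detections as tables rather than voxel stacks) are
bit-reproducible for a fixed config and seed; every stage logs the counts
that back the conservation invariants (detections, links, filtered tracks).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (KineticsConfig, SimulationConfig, TrackingConfig, ZoneConfig,
                     config_hash, dump_toml, load_toml, simulation_config_from_dict,
                     _from_plain)
from .kinetics import add_coordinated_motility, cell_feature_summary, compute_kinematics
from .maps import add_zones, spatiotemporal_map
from .simulate import render_frames, simulate_root
from .track import filter_tracks, link_tracks

__all__ = ["run_pipeline", "validate_io", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "track", "kinetics", "maps", "features")

SCHEMAS = {
    "tracks": {
        "required": ["track_id", "frame", "t_h", "x_um", "y_um", "z_um", "gap_flag"],
        "coords": ["x_um", "y_um", "z_um"],
        "per_track_monotone": True,
    },
    "detections": {
        "required": ["frame", "t_h", "x_um", "y_um", "z_um"],
        "coords": ["x_um", "y_um", "z_um"],
        "per_track_monotone": False,
    },
    "kinematics": {
        "required": ["track_id", "frame", "t_h", "vx", "vy", "vz", "speed"],
        "coords": [],
        "per_track_monotone": True,
    },
}


def validate_io(table, schema: str) -> list[str]:
    """Validate a table (path or DataFrame) against a named schema.

    Returns a list of human-readable violations; empty means valid.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    spec = SCHEMAS[schema]
    violations = []
    for col in spec["required"]:
        if col not in table.columns:
            violations.append(f"missing column {col!r}")
    for col in spec["coords"]:
        if col in table.columns:
            bad = np.flatnonzero(~np.isfinite(table[col].to_numpy(float)))
            for row in bad[:20]:
                violations.append(f"non-finite {col} at row {int(row)}")
    if spec["per_track_monotone"] and "track_id" in table.columns and "frame" in table.columns:
        for tid, g in table.groupby("track_id"):
            frames = g["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                violations.append(f"non-monotone frames within track {tid}")
    return violations


def _build_configs(config: dict):
    sim = simulation_config_from_dict(config.get("simulate", {}))
    trk = _from_plain(TrackingConfig, config.get("track", {}))
    trk.validate()
    kin = _from_plain(KineticsConfig, config.get("kinetics", {}))
    kin.validate()
    zone = _from_plain(ZoneConfig, config.get("zones", {}))
    zone.validate()
    return sim, trk, kin, zone


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 stages: tuple[str, ...] = STAGES, seed: int | None = None) -> dict:
    """Run the point-mode pipeline and write stage artifacts plus a manifest.

    ``config`` is a nested dict or a TOML path with blocks [simulate],
    [track], [kinetics], [zones]. ``seed`` overrides the simulate seed.
    Stage dependencies are resolved from disk: a stage that needs an
    upstream table reads it from ``outdir`` if not produced in this run,
    and raises a clear error naming the missing stage otherwise.
    """
    if isinstance(config, (str, Path)):
        config = load_toml(config)
    for key in config:
        if key not in ("simulate", "track", "kinetics", "zones", "maps", "scenario"):
            raise KeyError(f"unknown config block {key!r}")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg, trk_cfg, kin_cfg, zone_cfg = _build_configs(config)
    if seed is not None:
        sim_cfg.seed = int(seed)

    artifacts: dict[str, Path] = {}

    def need(name: str, producer: str) -> pd.DataFrame:
        path = outdir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage needs {name!r} but it was not produced; run stage {producer!r} first")
        return pd.read_csv(path)

    tracks = kin = None
    if "simulate" in stages:
        truth = simulate_root(sim_cfg, scenario=config.get("scenario", {}).get("name"),
                              scenario_params={k: v for k, v in config.get("scenario", {}).items()
                                               if k != "name"})
        frames = render_frames(truth)
        truth.to_csv(outdir / "truth.csv")
        frames.to_csv(outdir / "detections.csv")
        frames.bookkeeping.to_csv(outdir / "bookkeeping.csv", index=False)
        dump_toml(sim_cfg, outdir / "simulate_config.toml")
        artifacts["truth"] = outdir / "truth.csv"
        artifacts["detections"] = outdir / "detections.csv"
    if "track" in stages:
        from .simulate import FrameSet

        det = need("detections", "simulate")
        frames = FrameSet(detections=det, frame_interval_min=sim_cfg.frame_interval_min)
        tracks = link_tracks(frames, trk_cfg)
        tracks = filter_tracks(tracks, trk_cfg, sim_cfg.frame_interval_min)
        tracks.to_csv(outdir / "tracks.csv", index=False)
        artifacts["tracks"] = outdir / "tracks.csv"
    if "kinetics" in stages:
        tracks = tracks if tracks is not None else need("tracks", "track")
        kin = compute_kinematics(tracks, sim_cfg.frame_interval_min, kin_cfg)
        kin = add_coordinated_motility(kin, kin_cfg)
        kin = add_zones(kin, zone_cfg, tip_y_config=sim_cfg.tip_position[1])
        kin.to_csv(outdir / "kinematics.csv", index=False)
        artifacts["kinematics"] = outdir / "kinematics.csv"
    if "maps" in stages:
        kin = kin if kin is not None else need("kinematics", "kinetics")
        for stat in ("vy", "speed", "cm"):
            if stat not in kin:
                continue
            m = spatiotemporal_map(kin.dropna(subset=[stat]), stat)
            m.to_frame().to_csv(outdir / f"map_{stat}.csv")
            m.plot(outdir / f"map_{stat}.png")
            artifacts[f"map_{stat}"] = outdir / f"map_{stat}.csv"
    if "features" in stages:
        kin = kin if kin is not None else need("kinematics", "kinetics")
        feats = cell_feature_summary(kin, sim_cfg.frame_interval_min)
        feats.to_csv(outdir / "features.csv")
        artifacts["features"] = outdir / "features.csv"

    manifest = {
        "rootkin_version": __version__,
        "python": platform.python_version(),
        "seed": sim_cfg.seed,
        "config_hash": config_hash(config),
        "stages": list(stages),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
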