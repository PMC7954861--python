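"""Configuration objects for the root morphokinetics pipeline.

All lengths are micrometres, all internal times are hours; the acquisition
frame interval is stored in minutes (the unit microscope software reports)
and converted exactly once, on access.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "ConfigError",
    "AxialProfile",
    "SkewConfig",
    "NoiseConfig",
    "ReporterConfig",
    "SimulationConfig",
    "DetectionConfig",
    "TrackingConfig",
    "KineticsConfig",
    "ZoneConfig",
    "load_toml",
    "dump_toml",
    "config_hash",
]

# Default developmental-zone boundaries (axial distance from the tip, µm).
DEFAULT_MERISTEM_END = 250.0
DEFAULT_ELONGATION_END = 700.0


class ConfigError(ValueError):
    """Raised for invalid or non-finite configuration values."""


def _check_finite(obj: Any, path: str = "") -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            _check_finite(getattr(obj, f.name), f"{path}{f.name}.")
    elif isinstance(obj, (tuple, list)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}{i}.")
    elif isinstance(obj, float):
        if not math.isfinite(obj):
            raise ConfigError(f"non-finite value at {path.rstrip('.')}")


@dataclass
class AxialProfile:
    """Sigmoidal axial velocity field in the tip frame.

    v(y) = v_plateau * s((y - y_mid) / width) with s the logistic function:
    near zero at the tip, saturating at the plateau shootward of the
    meristem, so that elongation-zone nuclei move steadily at v_plateau.
    """

    v_plateau: float = 50.0  # µm/h
    y_mid: float = 100.0  # µm from tip
    width: float = 40.0  # µm

    def velocity(self, y):
        import numpy as np

        return self.v_plateau / (1.0 + np.exp(-(np.asarray(y, float) - self.y_mid) / self.width))


@dataclass
class SkewConfig:
    """Meristem skewing as a rigid twist about a tilted axis.

    Nuclei within ``meristem_extent`` of the tip rotate at ``omega`` about
    an axis tilted ``axis_tilt_deg`` from the root axis, producing
    anti-parallel lateral velocities on opposite flanks of the root.
    The default omega is calibrated so the quadratic-mean lateral speed of
    meristem nuclei exceeds the elongation zone by ~10 µm/h at the default
    root radius (omega * R / sqrt(2) = 10).
    """

    omega: float = 10.0 * math.sqrt(2.0) / 60.0  # rad/h
    axis_tilt_deg: float = 5.0
    meristem_extent: float = 250.0  # µm from tip


@dataclass
class NoiseConfig:
    jitter_sd: float = 0.5  # µm, isotropic detection jitter
    dropout_rate: float = 0.02  # per nucleus per frame
    false_positive_rate: float = 0.0  # expected spurious detections per frame
    intensity_noise_sd: float = 2.0  # au, additive channel noise


@dataclass
class ReporterConfig:
    """Phenomenological auxin-response reporter (DR5-like) dynamics.

    Intensity = baseline + amplitude * g(t) * exp(-(y-origin)^2 / 2w^2)
    with g(t) = 0 before ``onset_delay_h`` and a saturating exponential rise
    afterwards.
    """

    onset_delay_h: float = 2.5
    rise_time_h: float = 1.5
    spatial_origin_um: float = 400.0
    spatial_width_um: float = 150.0
    amplitude: float = 100.0
    baseline: float = 10.0


@dataclass
class SimulationConfig:
    root_radius: float = 60.0  # µm
    root_length: float = 1000.0  # µm of seeded tissue from the tip
    tip_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axial_profile: AxialProfile = field(default_factory=AxialProfile)
    skew: SkewConfig = field(default_factory=SkewConfig)
    division_rate: float = 0.05  # events/cell/h, meristem only
    n_nuclei: int = 1000
    frame_interval_min: float = 8.75
    n_frames: int = 40
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    zones: tuple[float, float] = (DEFAULT_MERISTEM_END, DEFAULT_ELONGATION_END)
    scenario: str = "control"
    seed: int = 0

    @property
    def dt_h(self) -> float:
        return self.frame_interval_min / 60.0

    def validate(self) -> None:
        _check_finite(self)
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.axial_profile.width <= 0:
            raise ConfigError("axial_profile.width must be > 0")
        if not (0 <= self.noise.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not (0 <= self.noise.false_positive_rate < 1e6):
            raise ConfigError("false_positive_rate must be >= 0")
        for name in ("division_rate", "root_radius", "root_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.skew.omega < 0 or self.skew.meristem_extent < 0:
            raise ConfigError("skew rates/extents must be >= 0")
        if not (0 < self.zones[0] < self.zones[1]):
            raise ConfigError("zone boundaries must satisfy 0 < meristem_end < elongation_end")
        if self.n_nuclei < 1:
            raise ConfigError("n_nuclei must be >= 1")


@dataclass
class DetectionConfig:
    """Surface-style nucleus detection parameters.

    The names mirror the microscope-software vocabulary: a smoothing grain
    size, background elimination with a rolling sphere, a manual intensity
    threshold, region growing to an estimated nucleus diameter, and quality
    / voxel-count minima. The quality statistic here is the integrated
    background-corrected intensity of a component; the published
    instrument-scale minima (5,000-15,000 quality, 10,000 voxels) must be
    re-calibrated per dataset and the defaults below are scaled for the
    synthetic renderings.
    """

    grain_size_um: float = 1.5
    background_sphere_diameter_um: float = 6.23
    manual_threshold: float = 20.0
    region_growing_diameter_um: float = 8.30
    quality_min: float = 50.0
    min_voxels: int = 5


@dataclass
class TrackingConfig:
    max_distance: float = 12.0  # µm, gate for frame-to-frame links
    max_gap: int = 3  # frames a track may bridge without a detection
    min_duration_s: float = 3600.0
    motion_model: str = "constant_velocity"  # or "none"
    assignment: str = "hungarian"  # or "greedy"

    def validate(self) -> None:
        _check_finite(self)
        if self.max_distance <= 0:
            raise ConfigError("max_distance must be > 0")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.min_duration_s < 0:
            raise ConfigError("min_duration_s must be >= 0")
        if self.motion_model not in ("none", "constant_velocity"):
            raise ConfigError(f"unknown motion model {self.motion_model!r}")
        if self.assignment not in ("hungarian", "greedy"):
            raise ConfigError(f"unknown assignment {self.assignment!r}")


@dataclass
class KineticsConfig:
    differencing: str = "central"  # or "forward"
    cm_radius: float = 200.0  # µm, coordinated-motility neighbourhood
    cm_min_neighbors: int = 3
    frame: str = "lab"  # or "tip"

    def validate(self) -> None:
        if self.cm_radius <= 0:
            raise ConfigError("cm_radius must be > 0")
        if self.differencing not in ("central", "forward"):
            raise ConfigError(f"unknown differencing {self.differencing!r}")


@dataclass
class ZoneConfig:
    meristem_end: float = DEFAULT_MERISTEM_END
    elongation_end: float = DEFAULT_ELONGATION_END
    tip_mode: str = "quantile"  # or "config"
    tip_quantile: float = 0.02

    def validate(self) -> None:
        if not (0 < self.meristem_end < self.elongation_end):
            raise ConfigError("need 0 < meristem_end < elongation_end")


# ---------------------------------------------------------------------------
# TOML round-trip helpers


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r} for {cls.__name__}")
        ftype = fields[key].type
        if isinstance(value, dict):
            sub = {
                "axial_profile": AxialProfile,
                "skew": SkewConfig,
                "noise": NoiseConfig,
                "reporter": ReporterConfig,
            }.get(key)
            if sub is None:
                raise ConfigError(f"unexpected table {key!r}")
            value = _from_plain(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _emit_toml(data: dict, prefix: str = "") -> list[str]:
    # minimal emitter: scalars and lists first, then nested tables
    lines = []
    tables = []
    for key, value in data.items():
        if isinstance(value, dict):
            tables.append((key, value))
        elif isinstance(value, bool):
            lines.append(f"{key} = {'true' if value else 'false'}")
        elif isinstance(value, (int, float)):
            lines.append(f"{key} = {value!r}")
        elif isinstance(value, str):
            lines.append(f"{key} = {json.dumps(value)}")
        elif isinstance(value, (list, tuple)):
            lines.append(f"{key} = [{', '.join(repr(float(v)) for v in value)}]")
        else:
            raise ConfigError(f"cannot serialise {key!r} of type {type(value).__name__}")
    for key, value in tables:
        name = f"{prefix}{key}"
        lines.append(f"\n[{name}]")
        lines.extend(_emit_toml(value, prefix=f"{name}."))
    return lines


def dump_toml(config, path=None) -> str:
    """Serialise a config dataclass (or plain dict) to TOML text."""
    data = _to_plain(config) if dataclasses.is_dataclass(config) else config
    text = "\n".join(_emit_toml(data)) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    cfg = _from_plain(SimulationConfig, data)
    cfg.validate()
    return cfg


def config_hash(config) -> str:
    """Stable hash of a configuration for run manifests."""
    data = _to_plain(config) if dataclasses.is_dataclass(config) else config
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
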