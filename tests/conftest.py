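import dataclasses

import numpy as np
import pandas as pd
import pytest

from rootkin.config import NoiseConfig, SimulationConfig
from rootkin.simulate import FrameSet, simulate_root


def make_frameset(frames_positions, dt_min=8.75, true_ids=None):
    """Build a point-mode FrameSet from a list of per-frame (n, 3) arrays."""
    rows = []
    for f, pos in enumerate(frames_positions):
        pos = np.atleast_2d(np.asarray(pos, float))
        if pos.size == 0:
            continue
        ids = true_ids[f] if true_ids is not None else -np.ones(len(pos), int)
        for k, p in enumerate(pos):
            rows.append((f, f * dt_min / 60.0, p[0], p[1], p[2], int(ids[k])))
    det = pd.DataFrame(rows, columns=["frame", "t_h", "x_um", "y_um", "z_um", "true_id"])
    # keep n_frames correct even when trailing frames are empty
    if len(frames_positions) and not len(det[det["frame"] == len(frames_positions) - 1]):
        det = pd.concat([det, pd.DataFrame([{
            "frame": len(frames_positions) - 1,
            "t_h": (len(frames_positions) - 1) * dt_min / 60.0,
            "x_um": np.nan, "y_um": np.nan, "z_um": np.nan, "true_id": -1,
        }])], ignore_index=True).dropna()
    return FrameSet(detections=det, frame_interval_min=dt_min)


@pytest.fixture(scope="session")
def small_config():
    cfg = SimulationConfig(seed=11, n_nuclei=150, n_frames=15, division_rate=0.0)
    cfg.noise = NoiseConfig(jitter_sd=0.5, dropout_rate=0.02, false_positive_rate=0.0)
    return cfg


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_root(small_config)


@pytest.fixture(scope="session")
def skew_truth():
    cfg = SimulationConfig(seed=13, n_nuclei=250, n_frames=12, division_rate=0.0)
    cfg.noise = NoiseConfig(jitter_sd=0.0, dropout_rate=0.0)
    return simulate_root(cfg)


@pytest.fixture(scope="session")
def noiseless_config():
    cfg = SimulationConfig(seed=19, n_nuclei=80, n_frames=10, division_rate=0.0)
    cfg.noise = NoiseConfig(jitter_sd=0.0, dropout_rate=0.0, false_positive_rate=0.0,
                            intensity_noise_sd=0.0)
    return cfg


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_config):
    return simulate_root(noiseless_config)


def single_nucleus_config(y0, **kwargs):
    """A one-nucleus, no-noise configuration with the nucleus near y0.

    The seeded position is random; callers that need an exact y place the
    nucleus by overriding root_length to a thin slab around y0.
    """
    cfg = SimulationConfig(n_nuclei=1, division_rate=0.0, root_length=1.0, **kwargs)
    cfg.skew = dataclasses.replace(cfg.skew, omega=0.0)
    cfg.noise = NoiseConfig(jitter_sd=0.0, dropout_rate=0.0, false_positive_rate=0.0)
    return cfg
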