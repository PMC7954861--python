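"""Frame-to-frame track linking with gap closing and duration filtering.

The linker follows the autoregressive-motion family of particle trackers:
each open track predicts its next position by order-1 constant-velocity
extrapolation from its last two linked samples (its last position when only
one sample exists), candidate links are gated at ``max_distance`` (scaled by
gap length + 1 when bridging missed detections), and the per-frame
assignment is solved globally (Hungarian) or greedily. Tracks shorter than
``min_duration_s`` are discarded afterwards, mirroring the duration filter
applied in the published surface-tracking pipeline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import TrackingConfig
from .simulate import FrameSet, GroundTruth

__all__ = ["link_tracks", "filter_tracks", "match_to_truth", "track_durations"]

log = logging.getLogger(__name__)

_BIG = 1e9

TRACK_COLUMNS = [
    "track_id", "frame", "t_h", "x_um", "y_um", "z_um", "gap_flag", "true_id",
]


@dataclass
class _OpenTrack:
    track_id: int
    frames: list = field(default_factory=list)  # linked frame indices
    positions: list = field(default_factory=list)  # linked positions
    det_rows: list = field(default_factory=list)  # detections row index per linked frame
    gap: int = 0  # frames since last link

    def predict(self, target_frame: int, constant_velocity: bool) -> np.ndarray:
        p_last = self.positions[-1]
        if constant_velocity and len(self.positions) >= 2:
            v = (self.positions[-1] - self.positions[-2]) / (self.frames[-1] - self.frames[-2])
            return p_last + v * (target_frame - self.frames[-1])
        return p_last


def _assign(cost: np.ndarray, gates: np.ndarray, assignment: str, birth_cost: float):
    """Gated assignment between open tracks (rows) and detections (cols).

    Returns (track_idx, det_idx) pairs with cost strictly below the track's
    gate. The Hungarian form augments the matrix with per-track "miss" and
    per-detection "birth" alternatives priced at the gate, so a link is made
    only when it beats both alternatives.
    """
    n_t, n_d = cost.shape
    if n_t == 0 or n_d == 0:
        return []
    if assignment == "greedy":
        pairs = []
        order = np.argsort(cost, axis=None, kind="stable")
        used_t, used_d = set(), set()
        for flat in order:
            i, j = divmod(int(flat), n_d)
            if cost[i, j] >= gates[i]:
                break
            if i in used_t or j in used_d:
                continue
            pairs.append((i, j))
            used_t.add(i); used_d.add(j)
        return pairs
    full = np.full((n_t + n_d, n_d + n_t), _BIG)
    full[:n_t, :n_d] = np.where(cost < gates[:, None], cost, _BIG)
    full[:n_t, n_d:] = np.where(np.eye(n_t, dtype=bool), gates[:, None] * np.ones(n_t), _BIG)
    full[n_t:, :n_d] = np.where(np.eye(n_d, dtype=bool), birth_cost, _BIG)
    full[n_t:, n_d:] = 0.0
    rows, cols = linear_sum_assignment(full)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)
             if i < n_t and j < n_d and cost[i, j] < gates[i]]
    return pairs


def link_tracks(frames: FrameSet, config: TrackingConfig | None = None) -> pd.DataFrame:
    """Link a FrameSet's detections into tracks.

    Returns a track table with one row per (track, frame); bridged gap
    frames carry linearly interpolated positions with ``gap_flag`` True and
    ``true_id`` -1. Deterministic for a fixed detection order; with
    Hungarian assignment the result is order-independent up to cost ties.
    """
    config = config or TrackingConfig()
    config.validate()
    det = frames.detections
    if det.empty or frames.n_frames < 2:
        raise ValueError("need a FrameSet with at least 2 frames of detections")
    cv = config.motion_model == "constant_velocity"
    has_true = "true_id" in det.columns
    extra_cols = [c for c in det.columns if c.startswith("ch_")]

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = 0
    pos_cols = ["x_um", "y_um", "z_um"]

    frame_groups = {f: g for f, g in det.groupby("frame")}
    for f in range(frames.n_frames):
        g = frame_groups.get(f)
        positions = g[pos_cols].to_numpy() if g is not None else np.empty((0, 3))
        row_index = g.index.to_numpy() if g is not None else np.empty(0, int)
        if open_tracks and len(positions):
            preds = np.stack([tr.predict(f, cv) for tr in open_tracks])
            gates = np.array([config.max_distance * (tr.gap + 1) for tr in open_tracks])
            cost = np.linalg.norm(preds[:, None, :] - positions[None, :, :], axis=2)
            pairs = _assign(cost, gates, config.assignment, config.max_distance)
        else:
            pairs = []
        linked_t = {i for i, _ in pairs}
        linked_d = {j for _, j in pairs}
        for i, j in sorted(pairs):
            tr = open_tracks[i]
            tr.frames.append(f)
            tr.positions.append(positions[j])
            tr.det_rows.append(row_index[j])
            tr.gap = 0
        still_open = []
        for i, tr in enumerate(open_tracks):
            if i in linked_t:
                still_open.append(tr)
                continue
            tr.gap += 1
            if tr.gap > config.max_gap or f == frames.n_frames - 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for j in range(len(positions)):
            if j in linked_d:
                continue
            tr = _OpenTrack(track_id=next_id)
            next_id += 1
            tr.frames.append(f)
            tr.positions.append(positions[j])
            tr.det_rows.append(row_index[j])
            open_tracks.append(tr)
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr.track_id)

    rows = []
    dt_h = frames.dt_h
    for tr in closed:
        for k, (fr, p, ridx) in enumerate(zip(tr.frames, tr.positions, tr.det_rows)):
            if k > 0 and fr - tr.frames[k - 1] > 1:
                # fill the bridged gap with linear interpolation
                f0, p0 = tr.frames[k - 1], tr.positions[k - 1]
                for fg in range(f0 + 1, fr):
                    w = (fg - f0) / (fr - f0)
                    pg = (1 - w) * p0 + w * p
                    rows.append((tr.track_id, fg, fg * dt_h, pg[0], pg[1], pg[2],
                                 True, -1, None))
            rows.append((tr.track_id, fr, fr * dt_h, p[0], p[1], p[2], False,
                         int(det.at[ridx, "true_id"]) if has_true else -1, ridx))

    table = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["_det_row"])
    for c in extra_cols:
        vals = np.full(len(table), np.nan)
        mask = table["_det_row"].notna()
        vals[mask.to_numpy()] = det.loc[table.loc[mask, "_det_row"].astype(int), c].to_numpy()
        table[c] = vals
    table = table.drop(columns="_det_row")
    n_assigned = int((~table["gap_flag"]).sum())
    log.info("linked %d detections into %d tracks (%d gap rows)",
             n_assigned, table["track_id"].nunique(), int(table["gap_flag"].sum()))
    assert n_assigned == len(det), "every detection must appear in exactly one track"
    return table.sort_values(["track_id", "frame"]).reset_index(drop=True)


def track_durations(tracks: pd.DataFrame, frame_interval_min: float) -> pd.Series:
    """Track duration in seconds (frame span x frame interval)."""
    span = tracks.groupby("track_id")["frame"].agg(lambda s: s.max() - s.min())
    return span * frame_interval_min * 60.0


def filter_tracks(tracks: pd.DataFrame, config: TrackingConfig,
                  frame_interval_min: float) -> pd.DataFrame:
    """Drop tracks shorter than the configured minimum duration."""
    dur = track_durations(tracks, frame_interval_min)
    keep = dur[dur >= config.min_duration_s].index
    out = tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)
    log.info("duration filter: kept %d / %d tracks (min %.0f s)",
             len(keep), dur.size, config.min_duration_s)
    return out


def match_to_truth(tracks: pd.DataFrame, truth: GroundTruth,
                   tolerance_um: float = 5.0) -> dict:
    """Score linked tracks against simulator ground truth.

    A frame-to-frame link (consecutive non-gap samples of one track,
    including links bridging gaps) is correct when both detections stem from
    the same true nucleus. Returns link accuracy, identity-switch count and
    totals. ``tolerance_um`` is kept for API symmetry with image-based
    matching; point-mode detections carry their source id directly.
    """
    if "true_id" not in tracks.columns:
        raise ValueError("track table lacks true_id; was it built from simulated frames?")
    if tracks["frame"].max() > truth.n_frames - 1:
        raise ValueError("track frames exceed ground-truth frame count")
    total = 0
    correct = 0
    switches = 0
    for _, g in tracks[~tracks["gap_flag"]].groupby("track_id"):
        ids = g["true_id"].to_numpy()
        for a, b in zip(ids[:-1], ids[1:]):
            total += 1
            if a == b and a >= 0:
                correct += 1
            else:
                switches += 1
    return {
        "n_links": total,
        "n_correct": correct,
        "link_accuracy": correct / total if total else float("nan"),
        "identity_switches": switches,
    }
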