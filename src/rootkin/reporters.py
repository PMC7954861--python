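"""Reporter-channel quantification.

Covers the three quantifications used downstream of tracking: mean reporter
intensity inside a region of interest over time (DR5-like transcriptional
reporters, hours-scale onset), the DII/mDII ratio of the ratiometric R2D2
auxin sensor (auxin degrades DII but not the mutated mDII control, so a
falling ratio means rising auxin), and response-onset timing from an
intensity series.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROI", "quantify_roi", "dii_ratio", "onset_time"]


@dataclass
class ROI:
    """Axis-aligned box in µm: (min, max) per axis."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]
    label: str = "roi"

    def __post_init__(self):
        for name in ("x", "y", "z"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"ROI {name} range is empty: {lo} >= {hi}")

    def contains(self, df: pd.DataFrame) -> pd.Series:
        return ((df["x_um"] >= self.x[0]) & (df["x_um"] <= self.x[1])
                & (df["y_um"] >= self.y[0]) & (df["y_um"] <= self.y[1])
                & (df["z_um"] >= self.z[0]) & (df["z_um"] <= self.z[1]))


def _detections(frames) -> pd.DataFrame:
    return frames.detections if hasattr(frames, "detections") else frames


def quantify_roi(frames, roi: ROI, channel: str = "ch_reporter") -> pd.DataFrame:
    """Mean channel intensity of detections inside a ROI, per frame.

    Returns a tidy series (label, frame, t_h, value, n). Raises if the ROI
    never intersects the data or the channel is missing.
    """
    det = _detections(frames)
    if channel not in det.columns:
        raise KeyError(f"channel {channel!r} not in detections")
    inside = det[roi.contains(det)]
    if inside.empty:
        raise ValueError(f"ROI {roi.label!r} contains no detections in any frame")
    out = inside.groupby("frame").agg(t_h=("t_h", "first"), value=(channel, "mean"),
                                      n=(channel, "size")).reset_index()
    out.insert(0, "label", roi.label)
    return out


def dii_ratio(frames, roi: ROI, dii_channel: str = "ch_dii",
              mdii_channel: str = "ch_mdii") -> pd.DataFrame:
    """Per-frame mean DII / mean mDII ratio inside a ROI.

    Frames where the mDII mean is zero get a NaN ratio (undefined marker).
    Scaling both channels by a common factor leaves the ratio unchanged.
    """
    det = _detections(frames)
    for ch in (dii_channel, mdii_channel):
        if ch not in det.columns:
            raise KeyError(f"channel {ch!r} not in detections")
    inside = det[roi.contains(det)]
    if inside.empty:
        raise ValueError(f"ROI {roi.label!r} contains no detections in any frame")
    g = inside.groupby("frame").agg(t_h=("t_h", "first"), dii=(dii_channel, "mean"),
                                    mdii=(mdii_channel, "mean"), n=(dii_channel, "size"))
    with np.errstate(divide="ignore", invalid="ignore"):
        g["value"] = np.where(g["mdii"] > 0, g["dii"] / g["mdii"], np.nan)
    out = g.reset_index()[["frame", "t_h", "value", "n"]]
    out.insert(0, "label", roi.label)
    return out


def onset_time(series: pd.DataFrame, baseline_frames: int = 5, k: float = 3.0,
               persistence: int = 2) -> float:
    """Response-onset time (h) of an intensity series.

    Onset is the first time the value exceeds (baseline mean + k·sd) for
    ``persistence`` consecutive frames, where the baseline is the first
    ``baseline_frames`` frames. Returns NaN when the series never responds
    (including constant series, whose baseline sd is zero but which never
    leave the baseline level).
    """
    if baseline_frames < 3:
        raise ValueError("need at least 3 baseline frames")
    s = series.sort_values("frame")
    v = s["value"].to_numpy(float)
    t = s["t_h"].to_numpy(float)
    if len(v) <= baseline_frames:
        raise ValueError("series shorter than the baseline window")
    base = v[:baseline_frames]
    thresh = base.mean() + k * base.std(ddof=1)
    above = v > thresh
    run = 0
    for i in range(baseline_frames, len(v)):
        run = run + 1 if above[i] else 0
        if run >= persistence:
            return float(t[i - persistence + 1])
    return float("nan")
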