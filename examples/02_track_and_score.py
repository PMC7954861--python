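"""Render noisy detections, link them into tracks, and score against truth.

Acquisition noise (0.5 µm centroid jitter, 2% dropouts) is applied to the
ground truth, the gap-closing constant-velocity linker rebuilds tracks, and
the result is scored against the simulator's bookkeeping: the fraction of
frame-to-frame links that connect detections of the same true nucleus.
"""
from rootkin import SimulationConfig, TrackingConfig, simulate_root, render_frames
from rootkin.track import filter_tracks, link_tracks, match_to_truth

config = SimulationConfig(seed=1, n_nuclei=500, division_rate=0.0)
truth = simulate_root(config)
frames = render_frames(truth)
print(f"rendered {len(frames.detections)} detections over {frames.n_frames} frames")

tracking = TrackingConfig()  # 12 µm gate, 3-frame gaps, 3600 s duration filter
tracks = link_tracks(frames, tracking)
kept = filter_tracks(tracks, tracking, config.frame_interval_min)
report = match_to_truth(tracks, truth)

print(f"tracks: {tracks['track_id'].nunique()} linked, "
      f"{kept['track_id'].nunique()} pass the 1 h duration filter")
print(f"link accuracy: {report['link_accuracy']:.4f} "
      f"({report['identity_switches']} identity switches in {report['n_links']} links)")
print("\nAccuracy near 1.0 means the linker follows individual nuclei faithfully "
      "through jitter and missed detections.")
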