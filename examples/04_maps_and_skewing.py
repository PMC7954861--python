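"""Spatiotemporal maps and skewing quantification.

Builds the (axial distance × time) velocity map shown tip-up, fits a rigid
rotation to the meristem velocity field, and reports the model-free
meristem-vs-elongation lateral speed excess.
"""
import numpy as np

from rootkin import SimulationConfig, simulate_root
from rootkin.maps import skewing_rotation_fit, spatiotemporal_map, zone_lateral_excess

config = SimulationConfig(seed=1, n_nuclei=600, division_rate=0.0)
truth = simulate_root(config)
kin = truth.cells.rename(columns={"nucleus_id": "track_id"}).copy()
kin["dist_from_tip"] = kin["y_um"]
kin["gap_flag"] = False

vmap = spatiotemporal_map(kin, "vy", axial_bin_um=50.0)
print("velocity map shape (axial bins × frames):", vmap.matrix.shape)
centers = 0.5 * (vmap.axial_edges[:-1] + vmap.axial_edges[1:])
for c, row in list(zip(centers, vmap.matrix))[:10]:
    print(f"  {c:6.0f} µm from tip: mean vy = {np.nanmean(row):6.2f} µm/h")

mz = truth.cells[(truth.cells["frame"] == 0) & (truth.cells["zone"] == "MZ")]
fit = skewing_rotation_fit(mz[["x_um", "y_um", "z_um"]].to_numpy(),
                           mz[["vx", "vy", "vz"]].to_numpy())
print(f"\nrigid-rotation fit: |ω| = {fit['omega_mag']:.3f} rad/h "
      f"(configured {config.skew.omega:.3f}), residual RMS = {fit['residual_rms']:.3f} µm/h")

excess = zone_lateral_excess(kin, config.dt_h, debias=False)
print(f"meristem lateral excess over elongation zone: {excess['excess']:.2f} µm/h")
print("\nVelocity rises from the tip to the ~50 µm/h plateau; the fitted ω and the "
      "~10 µm/h lateral excess are two views of the same meristem skewing.")
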