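"""3D nucleus detection in voxel stacks.

A surface-style pipeline: Gaussian smoothing at a configured grain size,
background elimination by morphological opening with a rolling ball of the
configured diameter, a global manual threshold on the background-corrected
image, connected components, watershed region growing from component maxima
up to the estimated nucleus diameter, and quality / voxel-count minima.
Quality is the integrated background-corrected intensity of a component —
a transparent analogue of the proprietary surface quality statistic whose
published minima are instrument-scale values to be recalibrated per
dataset.

Stacks are ZYX with anisotropic voxel sizes in µm (z, y, x); centroids are
reported in world µm with x as the image x axis, y the axial image axis and
z the slice axis.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .config import DetectionConfig

__all__ = ["detect_nuclei", "morphology_features", "detect_frameset"]

DETECTION_COLUMNS = [
    "frame", "x_um", "y_um", "z_um", "voxel_count", "quality",
    "semi_a_um", "semi_b_um", "semi_c_um", "eccentricity", "area_um2",
]


def _ellipsoid_footprint(diameter_um: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    radii_vox = [max(1, int(round(diameter_um / 2.0 / v))) for v in voxel_size]
    zz, yy, xx = np.ogrid[[slice(-r, r + 1) for r in radii_vox]]
    return (zz / radii_vox[0]) ** 2 + (yy / radii_vox[1]) ** 2 + (xx / radii_vox[2]) ** 2 <= 1.0


def morphology_features(mask: np.ndarray, intensities: np.ndarray,
                        voxel_size: tuple[float, float, float]) -> dict:
    """Ellipsoid fit and projected area of one detection mask.

    Semi-axes come from intensity-weighted second moments via the uniform-
    ellipsoid relation (axis² = 5·λ); eccentricity uses the two largest
    semi-axes, sqrt(1 − (b/a)²). Area is the voxel footprint of the XY
    projection of the mask (µm²). A single-voxel mask gives eccentricity 0
    and one voxel footprint of area.
    """
    if not mask.any():
        raise ValueError("empty detection mask")
    vz, vy, vx = voxel_size
    idx = np.argwhere(mask)
    w = np.clip(intensities[mask], 0, None).astype(float)
    if w.sum() <= 0:
        w = np.ones(len(idx))
    coords = idx * np.array([vz, vy, vx])
    mean = np.average(coords, axis=0, weights=w)
    centered = coords - mean
    area_um2 = float(mask.any(axis=0).sum() * vy * vx)
    if len(idx) == 1:
        return {"semi_axes_um": (0.0, 0.0, 0.0), "eccentricity": 0.0,
                "area_um2": area_um2, "centroid_um": tuple(mean[::-1])}
    cov = (centered.T * w) @ centered / w.sum()
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    semi = np.sqrt(5.0 * np.clip(eigvals, 0, None))
    a, b = semi[0], semi[1]
    ecc = float(np.sqrt(1.0 - (b / a) ** 2)) if a > 0 else 0.0
    # centroid in world order (x, y, z); coords are (z, y, x)
    return {"semi_axes_um": tuple(semi), "eccentricity": ecc,
            "area_um2": area_um2, "centroid_um": (mean[2], mean[1], mean[0])}


def detect_nuclei(stack: np.ndarray, voxel_size: tuple[float, float, float],
                  config: DetectionConfig | None = None, frame: int = 0,
                  channels: dict[str, np.ndarray] | None = None,
                  origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> pd.DataFrame:
    """Detect nuclei in one ZYX stack; returns a detection table.

    An empty image yields zero detections (not an error). ``channels`` maps
    extra channel names to same-shape stacks whose mean intensity within
    each detection mask is reported as ``ch_<name>``. ``origin_um`` is the
    world (x, y, z) position of voxel (0, 0, 0), so centroids are reported
    in world µm.
    """
    config = config or DetectionConfig()
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (ZYX)")
    if voxel_size is None or len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
        raise ValueError("anisotropic voxel sizes (z, y, x) in µm are required")
    img = stack.astype(float)
    sigma_um = config.grain_size_um / 2.0
    sigma_vox = [sigma_um / v for v in voxel_size]
    smooth = ndimage.gaussian_filter(img, sigma=sigma_vox)
    fp = _ellipsoid_footprint(config.background_sphere_diameter_um, voxel_size)
    background = ndimage.grey_opening(smooth, footprint=fp)
    corrected = smooth - background
    mask = corrected > config.manual_threshold
    if not mask.any():
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    labels, n_comp = ndimage.label(mask)
    # region growing: watershed from per-component maxima, separating
    # touching nuclei at the configured estimated diameter
    min_dist_vox = max(1, int(round(config.region_growing_diameter_um
                                    / 2.0 / max(voxel_size))))
    peaks = peak_local_max(corrected, labels=labels, min_distance=min_dist_vox,
                           exclude_border=False)
    markers = np.zeros_like(labels)
    for i, pk in enumerate(peaks, start=1):
        markers[tuple(pk)] = i
    if markers.max() == 0:
        seg = labels
    else:
        seg = watershed(-corrected, markers=markers, mask=mask)
    rows = []
    for lab in range(1, seg.max() + 1):
        m = seg == lab
        count = int(m.sum())
        if count == 0 or count < config.min_voxels:
            continue
        quality = float(np.clip(corrected[m], 0, None).sum())
        if quality < config.quality_min:
            continue
        morph = morphology_features(m, corrected, voxel_size)
        cx, cy, cz = morph["centroid_um"]
        row = {
            "frame": frame, "x_um": cx + origin_um[0], "y_um": cy + origin_um[1],
            "z_um": cz + origin_um[2],
            "voxel_count": count, "quality": quality,
            "semi_a_um": morph["semi_axes_um"][0],
            "semi_b_um": morph["semi_axes_um"][1],
            "semi_c_um": morph["semi_axes_um"][2],
            "eccentricity": morph["eccentricity"],
            "area_um2": morph["area_um2"],
        }
        if channels:
            for name, ch in channels.items():
                row[f"ch_{name}"] = float(ch[m].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS
                        + [f"ch_{n}" for n in (channels or {})])


def detect_frameset(stacks, voxel_size, frame_interval_min: float,
                    config: DetectionConfig | None = None):
    """Run detection over a sequence of stacks and assemble a FrameSet."""
    from .simulate import FrameSet

    frames = []
    for i, stack in enumerate(stacks):
        det = detect_nuclei(stack, voxel_size, config, frame=i)
        det["t_h"] = i * frame_interval_min / 60.0
        det["true_id"] = -1
        frames.append(det)
    detections = pd.concat(frames, ignore_index=True)
    return FrameSet(detections=detections, frame_interval_min=frame_interval_min,
                    voxel_size_um=tuple(voxel_size), channels=())
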