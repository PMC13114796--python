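"""Auxiliary quantifications: stress-fibre crimp ratio and nuclear morphometrics.

The crimp ratio measures how curled a traced stress fibre is: the fibre's
arc length divided by its end-to-end chord (1 = perfectly straight, larger =
crimpier).  Nuclear metrics summarise a binary 3-D nuclear mask: maximum
cross-sectional area, slice aspect ratio, height, volume and convexity
(volume over convex-hull volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

__all__ = ["FibreTrace", "NucleusMask3D", "crimp_ratio", "nucleus_metrics"]


@dataclass
class FibreTrace:
    """Ordered polyline of one traced stress fibre, coordinates in μm."""

    polyline: np.ndarray  # (n, 2)
    fibre_id: int = 0

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (n, 2) array")
        if len(self.polyline) < 2:
            raise ValueError("polyline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("polyline has repeated consecutive points")


@dataclass
class NucleusMask3D:
    """Binary voxel mask of one nucleus with anisotropic voxel sizes (μm),
    axis order (z, y, x)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]  # (dz, dy, dx), μm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("nucleus mask must be 3-D")
        if self.voxel_size is None or len(self.voxel_size) != 3:
            raise ValueError("voxel_size (dz, dy, dx) is required")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


def crimp_ratio(trace: FibreTrace | np.ndarray) -> float:
    """Arc length over end-to-end chord of a fibre trace (≥ 1).

    Invariant to rigid motion and uniform scaling; raises for a closed loop
    (zero chord).
    """
    if not isinstance(trace, FibreTrace):
        trace = FibreTrace(np.asarray(trace))
    pts = trace.polyline
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord <= 1e-12 * max(arc, 1.0):
        raise ValueError("closed loop: chord length is zero")
    return arc / chord


def nucleus_metrics(mask: NucleusMask3D) -> dict[str, float]:
    """Morphometrics of a 3-D nuclear mask.

    cross_sectional_area (μm²) and aspect_ratio come from the maximum-area
    x–y slice (second-central-moment ellipse); height is the z extent,
    volume the voxel count × voxel volume, and convexity the volume divided
    by the convex-hull volume (≤ 1, equality for convex nuclei).
    """
    vox = mask.voxels
    if vox.sum() == 0:
        raise ValueError("empty nucleus mask")
    dz, dy, dx = mask.voxel_size

    slice_areas = vox.sum(axis=(1, 2))
    z_best = int(np.argmax(slice_areas))
    sl = vox[z_best]
    area = float(sl.sum()) * dy * dx

    rows, cols = np.nonzero(sl)
    pts = np.column_stack([cols * dx, rows * dy])
    cov = np.cov(pts, rowvar=False, bias=True) + np.diag([dx**2, dy**2]) / 12.0
    evals = np.linalg.eigvalsh(cov)
    aspect = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else np.nan

    z_idx = np.flatnonzero(slice_areas)
    height = float((z_idx[-1] - z_idx[0] + 1) * dz)
    volume = float(vox.sum()) * dz * dy * dx

    zz, yy, xx = np.nonzero(vox)
    cloud = np.column_stack([xx * dx, yy * dy, zz * dz])
    try:
        hull_volume = float(ConvexHull(cloud).volume)
    except Exception:
        hull_volume = 0.0
    if hull_volume <= 0:
        # a flat (single-layer) mask is degenerate for a centre-point hull;
        # pad each voxel with its 8 corners to give it finite thickness
        offsets = np.array(
            [[sx * dx / 2, sy * dy / 2, sz * dz / 2]
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        padded = (cloud[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        hull_volume = float(ConvexHull(padded).volume)
    convexity = min(1.0, volume / hull_volume) if hull_volume > 0 else np.nan

    return {
        "cross_sectional_area": area,
        "aspect_ratio": aspect,
        "height": height,
        "volume": volume,
        "convexity": convexity,
    }
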