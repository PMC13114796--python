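"""Per-cell 2-D shape descriptors computed from integer label masks.

The module turns a segmented label image into a table of six dimensionless
shape descriptors — roundness, extent, inscribed-circle ratio, aspect ratio,
symmetric ratio and signature-peak count — plus auxiliary geometry (area,
perimeter, long-axis length, leading-edge length).  Together the six
descriptors span the morphospace in which round, droplet-like and
spindle-like cells separate.

Boundaries are traced at sub-pixel resolution (marching squares), and the
perimeter is measured on that traced polygon rather than on pixel edges:
pixel-edge perimeters systematically overestimate boundary length and would
bias roundness (4πA/P²) downward.

Conventions: pixel centres sit at integer coordinates, origin top-left,
x rightward, y downward; 8-connectivity for cell regions; holes are filled
before measuring.  Areas are reported in μm² via ``pixel_size**2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from shapely import affinity
from shapely.geometry import LineString, Polygon
from sklearn.base import BaseEstimator, TransformerMixin
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "CellContour",
    "DescriptorConfig",
    "ShapeFeaturizer",
    "extract_contours",
    "roundness",
    "extent",
    "inscribed_circle_ratio",
    "aspect_ratio",
    "symmetric_ratio",
    "signature_peaks",
    "leading_edge_metrics",
    "featurize",
    "contour_from_polygon",
    "boundary_signature",
    "FEATURE_COLUMNS",
    "DESCRIPTOR_COLUMNS",
]

#: fixed output column order of the feature table
FEATURE_COLUMNS = [
    "cell_id",
    "area",
    "perimeter",
    "roundness",
    "extent",
    "inscribed_circle_ratio",
    "aspect_ratio",
    "symmetric_ratio",
    "signature_peaks",
    "long_axis_length",
    "leading_edge_length",
    "leading_edge_fraction",
]

#: the six descriptors used for clustering / morphospace work
DESCRIPTOR_COLUMNS = [
    "roundness",
    "extent",
    "inscribed_circle_ratio",
    "aspect_ratio",
    "symmetric_ratio",
    "signature_peaks",
]


@dataclass
class LabelMask:
    """2-D integer label image: 0 = background, k > 0 = cell instance k."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            if np.any(self.pixels != np.round(self.pixels)):
                raise ValueError("label mask must contain integers")
            self.pixels = self.pixels.astype(np.int32)
        if self.pixels.min() < 0:
            raise ValueError("label mask must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.pixels)
        return ids[ids > 0]


@dataclass
class CellContour:
    """Closed sub-pixel boundary of one cell, plus its pixel region.

    ``boundary`` is an (n, 2) array of (x, y) points in pixel units, closed
    implicitly (last point connects to first), positively oriented.  The
    pixel region is retained because several descriptors (inscribed circle,
    moments, fold symmetry) are defined on pixels, not on the polygon.
    """

    cell_id: int
    boundary: np.ndarray
    region: np.ndarray  # boolean crop of the (hole-filled) cell region
    region_offset: tuple[int, int]  # (row, col) of region[0, 0] in the mask
    pixel_size: float = 1.0
    had_holes: bool = False

    _polygon: Polygon | None = field(default=None, repr=False, compare=False)

    @property
    def polygon(self) -> Polygon:
        if self._polygon is None:
            poly = Polygon(self.boundary)
            if not poly.is_valid:
                poly = poly.buffer(0)
            self._polygon = poly
        return self._polygon

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    @property
    def area(self) -> float:
        """Region area in μm² (pixel count based)."""
        return float(self.region.sum()) * self.pixel_size**2

    @property
    def polygon_area(self) -> float:
        """Shoelace area of the traced boundary, μm²."""
        return self.polygon.area * self.pixel_size**2

    @property
    def perimeter(self) -> float:
        """Length of the traced boundary, μm."""
        return self.polygon.length * self.pixel_size

    def region_points(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel-centre coordinates of the region."""
        rows, cols = np.nonzero(self.region)
        r0, c0 = self.region_offset
        return np.column_stack([cols + c0, rows + r0]).astype(float)


@dataclass
class DescriptorConfig:
    """Tunable measurement parameters.

    min_area
        smallest cell to keep, μm².
    exclude_border
        drop cells touching the image border (their geometry is truncated).
    signature_bins
        angular resolution of the centroid-distance signature.
    signature_smooth_deg
        circular moving-average window, degrees.
    signature_prominence
        peak prominence as a fraction of the signature's range.
    signature_flat_tol
        signatures whose range is below this fraction of the mean radius are
        treated as flat (zero peaks).
    leading_edge_curvature_factor
        curvature threshold = factor / equivalent-circle radius; the default 2
        accepts arcs up to twice as curved as the equal-area circle.
    leading_edge_angle_tol_deg
        the arc's chord must be within this angle of perpendicular to the
        major axis.
    symmetric_ratio_raw
        if True report |region Δ folded| / A (can exceed 1) instead of the
        default bounded |region Δ folded| / (2A).
    """

    min_area: float = 20.0
    exclude_border: bool = True
    signature_bins: int = 360
    signature_smooth_deg: float = 5.0
    signature_prominence: float = 0.05
    signature_flat_tol: float = 0.02
    leading_edge_curvature_factor: float = 2.0
    leading_edge_angle_tol_deg: float = 45.0
    leading_edge_points: int = 256
    symmetric_ratio_raw: bool = False


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def extract_contours(
    mask: LabelMask | np.ndarray,
    min_area: float = 20.0,
    *,
    exclude_border: bool = True,
    pixel_size: float | None = None,
) -> list[CellContour]:
    """Trace the outer boundary of every retained cell in a label mask.

    Cells smaller than ``min_area`` (μm²) are dropped, as are cells touching
    the image border when ``exclude_border`` (their shape is truncated by the
    field of view).  Holes are filled; a cell with holes keeps its outer
    boundary only and is flagged.  An empty mask yields an empty list.
    """
    if not isinstance(mask, LabelMask):
        mask = LabelMask(np.asarray(mask), pixel_size or 1.0)
    px = mask.pixel_size
    out: list[CellContour] = []
    labels = mask.pixels
    h, w = labels.shape
    objects = ndimage.find_objects(labels)
    for cell_id in mask.cell_ids:
        sl = objects[cell_id - 1]
        if sl is None:  # pragma: no cover - find_objects guarantee
            continue
        region = labels[sl] == cell_id
        # keep the largest connected component only (8-connectivity)
        lab, n = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(region, lab, index=np.arange(1, n + 1))
            region = lab == (1 + int(np.argmax(sizes)))
        filled = ndimage.binary_fill_holes(region)
        had_holes = bool(filled.sum() > region.sum())
        if had_holes:
            logger.warning("cell %d has hole(s); keeping outer boundary", cell_id)
        area = filled.sum() * px**2
        if area < max(min_area, 4 * px**2):
            continue
        r0, c0 = sl[0].start, sl[1].start
        touches_border = (
            r0 == 0
            or c0 == 0
            or sl[0].stop == h
            or sl[1].stop == w
        ) and _touches_image_border(filled, sl, h, w)
        if exclude_border and touches_border:
            logger.warning("cell %d touches the image border; dropped", cell_id)
            continue
        boundary = _trace_boundary(filled, r0, c0)
        if boundary is None:
            continue
        out.append(
            CellContour(
                cell_id=int(cell_id),
                boundary=boundary,
                region=filled,
                region_offset=(r0, c0),
                pixel_size=px,
                had_holes=had_holes,
            )
        )
    return out


def _touches_image_border(region: np.ndarray, sl, h: int, w: int) -> bool:
    r, c = sl[0], sl[1]
    if r.start == 0 and region[0].any():
        return True
    if r.stop == h and region[-1].any():
        return True
    if c.start == 0 and region[:, 0].any():
        return True
    if c.stop == w and region[:, -1].any():
        return True
    return False


def _smooth_closed(pts: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of a closed polyline (suppresses the
    half-pixel staircase jitter of marching squares, which otherwise
    inflates the perimeter and every curvature estimate)."""
    if window <= 1 or len(pts) <= window:
        return pts
    kernel = np.ones(window) / window
    pad = window
    ext = np.vstack([pts[-pad:], pts, pts[:pad]])
    sm = np.column_stack(
        [np.convolve(ext[:, i], kernel, mode="same") for i in range(2)]
    )[pad:-pad]
    return sm


def _trace_boundary(
    filled: np.ndarray, r0: int, c0: int, smooth_window: int | None = None
) -> np.ndarray | None:
    """Marching-squares outer boundary in (x, y) mask coordinates."""
    padded = np.pad(filled.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer boundary is the longest
    # find_contours returns (row, col); shift for padding + crop offset
    rows = contour[:, 0] - 1 + r0
    cols = contour[:, 1] - 1 + c0
    pts = np.column_stack([cols, rows])
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        return None
    if smooth_window is None:
        # window proportional to contour length: keeps the smoothing scale a
        # fixed fraction of the shape, so descriptors survive upsampling
        smooth_window = max(5, len(pts) // 100)
    pts = _smooth_closed(pts, smooth_window)
    # enforce positive orientation under the standard math convention
    if _shoelace(pts) < 0:
        pts = pts[::-1]
    return pts


def contour_from_polygon(
    boundary: np.ndarray, pixel_size: float = 1.0, cell_id: int = 1
) -> CellContour:
    """Build a CellContour directly from an analytic closed polygon.

    The pixel region is rasterised from the polygon; useful for testing
    descriptors against closed-form shapes without rasterisation error in
    the boundary itself.
    """
    from skimage.draw import polygon as draw_polygon

    pts = np.asarray(boundary, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if _shoelace(pts) < 0:
        pts = pts[::-1]
    mins = pts.min(axis=0)
    shifted = pts - mins + 2.0
    shape = tuple(int(np.ceil(shifted[:, i].max())) + 3 for i in (1, 0))
    rr, cc = draw_polygon(shifted[:, 1], shifted[:, 0], shape=shape)
    region = np.zeros(shape, dtype=bool)
    region[rr, cc] = True
    return CellContour(
        cell_id=cell_id,
        boundary=shifted,
        region=region,
        region_offset=(0, 0),
        pixel_size=pixel_size,
    )


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# the six descriptors
# ---------------------------------------------------------------------------

def roundness(contour: CellContour) -> float:
    """4πA/P² — 1 for a circle, smaller for any other shape."""
    P = contour.perimeter
    if P <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    value = 4.0 * np.pi * contour.polygon_area / P**2
    return float(np.clip(value, np.finfo(float).tiny, 1.0))


def extent(contour: CellContour) -> float:
    """Cell pixels over the pixels of the axis-aligned bounding box, (0, 1].

    Computed on the pixel region (not the traced polygon): the descriptor is
    defined as a pixel ratio, and the pixel form is exactly invariant under
    integer upsampling.
    """
    region = contour.region
    rows, cols = np.nonzero(region)
    if rows.size == 0:
        raise ValueError("degenerate contour: empty region")
    bbox = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
    return float(np.clip(region.sum() / bbox, np.finfo(float).tiny, 1.0))


def inscribed_circle_ratio(contour: CellContour) -> float:
    """Area of the maximum inscribed circle over the cell area.

    The inscribed-circle radius is the maximum of the Euclidean distance
    transform of the region.
    """
    region = contour.region
    if region.sum() < 4:
        raise ValueError("region too small for a distance transform")
    # pad so a region filling its crop still sees background
    dist = ndimage.distance_transform_edt(np.pad(region, 1))
    r_max = float(dist.max())
    a_pix = float(region.sum())
    return float(np.clip(np.pi * r_max**2 / a_pix, np.finfo(float).tiny, 1.0))


def _second_moment_axes(points: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(major_len, minor_len, major_dir, minor_dir) of the moment-equivalent
    ellipse of a pixel-centre point cloud.

    Adds the 1/12 variance of a unit pixel so a single-pixel-wide line still
    has finite width, matching the normalised-second-central-moment ellipse
    convention used for raster regions.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty region")
    cov = np.cov(pts, rowvar=False, bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise ValueError("degenerate region: collinear pixels")
    minor = 4.0 * np.sqrt(evals[0])
    major = 4.0 * np.sqrt(evals[1])
    return major, minor, evecs[:, 1], evecs[:, 0]


def aspect_ratio(contour: CellContour) -> float:
    """Major/minor axis length of the moment-equivalent ellipse (≥ 1)."""
    major, minor, _, _ = _second_moment_axes(contour.region_points())
    return float(major / minor)


def long_axis_length(contour: CellContour) -> float:
    """Major-axis length of the moment-equivalent ellipse, μm."""
    major, _, _, _ = _second_moment_axes(contour.region_points())
    return float(major * contour.pixel_size)


def symmetric_ratio(contour: CellContour, *, raw: bool = False) -> float:
    """Area mismatch after folding the cell about its minor axis.

    The region is reflected across the line through the centroid along the
    minor-axis direction; the symmetric-difference area, normalised by twice
    the cell area, is returned (0 = perfect bilateral symmetry, bounded below
    1).  ``raw=True`` divides by the cell area instead (the unnormalised
    reading, which can reach 2 for fully disjoint folds).
    """
    poly = contour.polygon
    _, _, major_dir, _ = _second_moment_axes(contour.region_points())
    cx, cy = poly.centroid.x, poly.centroid.y
    # reflecting across the minor axis == negating the major-axis coordinate:
    # rotate so major axis is x, mirror x about the centroid, rotate back
    angle = np.degrees(np.arctan2(major_dir[1], major_dir[0]))
    rotated = affinity.rotate(poly, -angle, origin=(cx, cy))
    mirrored = affinity.scale(rotated, xfact=-1.0, yfact=1.0, origin=(cx, cy))
    folded = affinity.rotate(mirrored, angle, origin=(cx, cy))
    sym_diff = poly.symmetric_difference(folded).area
    denom = poly.area if raw else 2.0 * poly.area
    return float(sym_diff / denom)


def boundary_signature(contour: CellContour, n_bins: int = 360) -> np.ndarray:
    """Centroid-to-boundary distance sampled on a uniform angular grid.

    For each angle a ray is cast from the centroid and intersected with the
    boundary; the farthest intersection is recorded, which makes the
    signature well defined even for concave shapes (for which the boundary
    radius is multivalued in angle).
    """
    poly = contour.polygon
    c = poly.centroid
    if not poly.contains(c):
        logger.warning(
            "cell %d: centroid lies outside the region (highly concave)",
            contour.cell_id,
        )
    ring = LineString(list(poly.exterior.coords))
    # ray length safely beyond the shape
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0
    angles = np.linspace(0.0, 2.0 * np.pi, n_bins, endpoint=False)
    sig = np.empty(n_bins)
    for i, a in enumerate(angles):
        ray = LineString(
            [(c.x, c.y), (c.x + reach * np.cos(a), c.y + reach * np.sin(a))]
        )
        hit = ray.intersection(ring)
        if hit.is_empty:
            sig[i] = 0.0
            continue
        if hit.geom_type == "Point":
            d = hit.distance(c)
        else:
            d = max(g.distance(c) for g in getattr(hit, "geoms", [hit]))
        sig[i] = d
    return sig * contour.pixel_size


def signature_peaks(
    contour: CellContour,
    *,
    n_bins: int = 360,
    smooth_deg: float = 5.0,
    prominence: float = 0.05,
    flat_tol: float = 0.02,
) -> int:
    """Count peaks of the angular centroid-distance signature.

    The signature is smoothed with a circular moving average (``smooth_deg``
    window) and local maxima are counted with wrap-around topology and a
    minimum prominence of ``prominence`` × the signature's range.  A
    signature whose range is below ``flat_tol`` × mean radius is flat (a
    circle up to rasterisation noise) and yields zero peaks.
    """
    sig = boundary_signature(contour, n_bins)
    window = max(1, int(round(smooth_deg / (360.0 / n_bins))))
    if window > 1:
        kernel = np.ones(window) / window
        sig = np.convolve(np.concatenate([sig[-window:], sig, sig[:window]]), kernel, mode="same")[
            window:-window
        ]
    rng = sig.max() - sig.min()
    if rng < flat_tol * sig.mean():
        return 0
    tiled = np.concatenate([sig, sig, sig])
    peaks, _ = find_peaks(tiled, prominence=prominence * rng)
    circular = np.unique(peaks[(peaks >= n_bins) & (peaks < 2 * n_bins)] - n_bins)
    if circular.size == 0:
        return 0
    # merge maxima closer than 10° circularly: a flat-topped peak of a
    # rasterised boundary often splits into twins after smoothing
    min_dist = max(window, n_bins // 36)
    gaps = np.diff(circular, append=circular[0] + n_bins)
    n_groups = int((gaps >= min_dist).sum())
    return max(1, n_groups)


# ---------------------------------------------------------------------------
# leading edge
# ---------------------------------------------------------------------------

def _resample_closed(boundary: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced in arc length."""
    pts = np.vstack([boundary, boundary[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def _discrete_curvature(pts: np.ndarray, stencil: int = 1) -> np.ndarray:
    """Unsigned curvature at each point of a closed equally-spaced polyline
    via the circumscribed circle through points ``stencil`` steps apart.

    A wider stencil trades spatial resolution for robustness to the
    sub-pixel jitter a rasterised boundary carries (three-point curvature
    noise scales as 1/ds², so pixel-scale spacing is hopeless)."""
    p_prev = np.roll(pts, stencil, axis=0)
    p_next = np.roll(pts, -stencil, axis=0)
    a = np.linalg.norm(pts - p_prev, axis=1)
    b = np.linalg.norm(p_next - pts, axis=1)
    c = np.linalg.norm(p_next - p_prev, axis=1)
    cross = (pts[:, 0] - p_prev[:, 0]) * (p_next[:, 1] - p_prev[:, 1]) - (
        pts[:, 1] - p_prev[:, 1]
    ) * (p_next[:, 0] - p_prev[:, 0])
    area2 = np.abs(cross)
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return k


def leading_edge_metrics(
    contour: CellContour,
    *,
    curvature_factor: float = 2.0,
    angle_tol_deg: float = 45.0,
    n_points: int = 256,
    smooth_window: int = 9,
) -> tuple[float, float]:
    """Length and perimeter fraction of the lamellipodium-like front.

    The leading edge is the longest contiguous boundary arc whose local
    curvature stays below ``curvature_factor / r_eq`` (r_eq the equal-area
    circle radius) and whose chord is within ``angle_tol_deg`` of
    perpendicular to the major axis — a smooth wide front facing along the
    elongation axis.  If the whole boundary passes the curvature test (a
    near-circular cell) the full perimeter qualifies and the fraction is 1.
    Returns (0, 0) when no arc qualifies.
    """
    pts = _resample_closed(contour.boundary, n_points)
    pts = _smooth_closed(pts, max(3, n_points // 48))
    k = _discrete_curvature(pts, stencil=max(2, n_points // 48))
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        k = np.convolve(np.concatenate([k[-smooth_window:], k, k[:smooth_window]]), kernel, mode="same")[
            smooth_window:-smooth_window
        ]
    area_px = contour.polygon.area
    r_eq = np.sqrt(area_px / np.pi)
    threshold = curvature_factor / r_eq
    ok = k < threshold
    if ok.all():
        return contour.perimeter, 1.0
    if not ok.any():
        return 0.0, 0.0
    _, _, major_dir, _ = _second_moment_axes(contour.region_points())
    arcs = _circular_runs(ok)
    ds = contour.polygon.length / n_points  # arc step, px
    best_len = 0.0
    for start, length in arcs:
        idx = np.arange(start, start + length) % n_points
        chord = pts[idx[-1]] - pts[idx[0]]
        norm = np.linalg.norm(chord)
        if norm > 1e-9:
            cosang = abs(np.dot(chord / norm, major_dir))
            # chord should be ~perpendicular to the major axis
            if cosang > np.cos(np.radians(90.0 - angle_tol_deg)):
                continue
        arc_len = length * ds
        best_len = max(best_len, arc_len)
    if best_len == 0.0:
        return 0.0, 0.0
    length_um = best_len * contour.pixel_size
    return float(length_um), float(length_um / contour.perimeter)


def _circular_runs(ok: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True in a circular boolean array."""
    n = len(ok)
    if ok.all():
        return [(0, n)]
    # rotate so position 0 is False, then find linear runs
    first_false = int(np.argmin(ok))
    rolled = np.roll(ok, -first_false)
    runs = []
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((start + first_false) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + first_false) % n, n - start))
    return runs


# ---------------------------------------------------------------------------
# batch featurization
# ---------------------------------------------------------------------------

def featurize(
    mask: LabelMask | np.ndarray,
    config: DescriptorConfig | None = None,
    *,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Compute the full feature table for every retained cell in a mask.

    One row per cell in ascending cell-id order, columns as in
    ``FEATURE_COLUMNS``.  A per-cell failure flags the row (NaN descriptors,
    ``error`` column) instead of aborting the batch.
    """
    cfg = config or DescriptorConfig()
    contours = extract_contours(
        mask,
        cfg.min_area,
        exclude_border=cfg.exclude_border,
        pixel_size=pixel_size,
    )
    rows = []
    for ct in sorted(contours, key=lambda c: c.cell_id):
        row: dict = {"cell_id": ct.cell_id}
        try:
            row["area"] = ct.area
            row["perimeter"] = ct.perimeter
            row["roundness"] = roundness(ct)
            row["extent"] = extent(ct)
            row["inscribed_circle_ratio"] = inscribed_circle_ratio(ct)
            row["aspect_ratio"] = aspect_ratio(ct)
            row["symmetric_ratio"] = symmetric_ratio(ct, raw=cfg.symmetric_ratio_raw)
            row["signature_peaks"] = signature_peaks(
                ct,
                n_bins=cfg.signature_bins,
                smooth_deg=cfg.signature_smooth_deg,
                prominence=cfg.signature_prominence,
                flat_tol=cfg.signature_flat_tol,
            )
            row["long_axis_length"] = long_axis_length(ct)
            le_len, le_frac = leading_edge_metrics(
                ct,
                curvature_factor=cfg.leading_edge_curvature_factor,
                angle_tol_deg=cfg.leading_edge_angle_tol_deg,
                n_points=cfg.leading_edge_points,
            )
            row["leading_edge_length"] = le_len
            row["leading_edge_fraction"] = le_frac
        except Exception as exc:  # flag, never abort the batch
            logger.warning("cell %d failed: %s", ct.cell_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS + (["error"] if any("error" in r for r in rows) else []))
    if table.empty:
        table = pd.DataFrame(columns=FEATURE_COLUMNS)
    return table


class ShapeFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping label masks to per-cell shape-feature tables.

    Stateless (``fit`` is a no-op); exists so featurization composes with
    sklearn pipelines and ``get_params``/``set_params`` configuration.

    Parameters mirror :class:`DescriptorConfig`.
    """

    def __init__(
        self,
        min_area: float = 20.0,
        exclude_border: bool = True,
        signature_bins: int = 360,
        signature_smooth_deg: float = 5.0,
        signature_prominence: float = 0.05,
        leading_edge_curvature_factor: float = 2.0,
        symmetric_ratio_raw: bool = False,
    ) -> None:
        self.min_area = min_area
        self.exclude_border = exclude_border
        self.signature_bins = signature_bins
        self.signature_smooth_deg = signature_smooth_deg
        self.signature_prominence = signature_prominence
        self.leading_edge_curvature_factor = leading_edge_curvature_factor
        self.symmetric_ratio_raw = symmetric_ratio_raw

    def _config(self) -> DescriptorConfig:
        return DescriptorConfig(
            min_area=self.min_area,
            exclude_border=self.exclude_border,
            signature_bins=self.signature_bins,
            signature_smooth_deg=self.signature_smooth_deg,
            signature_prominence=self.signature_prominence,
            leading_edge_curvature_factor=self.leading_edge_curvature_factor,
            symmetric_ratio_raw=self.symmetric_ratio_raw,
        )

    def fit(self, X, y=None):  # noqa: D102 - sklearn protocol
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: a LabelMask/array or a list of them; returns one concatenated
        table with a ``mask_index`` column when several masks are given."""
        cfg = self._config()
        if isinstance(X, (LabelMask, np.ndarray)):
            return featurize(X, cfg)
        tables = []
        for i, m in enumerate(X):
            t = featurize(m, cfg)
            t.insert(0, "mask_index", i)
            tables.append(t)
        if not tables:
            return pd.DataFrame(columns=["mask_index"] + FEATURE_COLUMNS)
        return pd.concat(tables, ignore_index=True)
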