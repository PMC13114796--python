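"""Synthetic inputs with known ground truth for the whole pipeline.

Generates the three cell-shape archetypes seen in cultured breast-cancer
populations — round, droplet (teardrop with a flat wide front) and spindle
(elongated lens) — as rasterised label masks with per-cell truth records,
plus wavy fibre polylines and ellipsoidal nuclear volumes.  Everything is
seed-deterministic.

The droplet is a circle-to-tail blend: the front half is a superellipse
(exponent > 2 flattens the leading edge) and the rear tapers with a power
profile, which makes the shape asymmetric about its minor axis — exactly
the property the symmetric-ratio descriptor is designed to pick up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .aux_metrics import FibreTrace, NucleusMask3D
from .shape_descriptors import LabelMask

__all__ = [
    "PopulationSpec",
    "ARCHETYPES",
    "make_archetype_mask",
    "make_population",
    "make_elongation_dominated_features",
    "make_fibre",
    "make_nucleus",
]

ARCHETYPES = ("round", "droplet", "spindle")

#: per-class aspect-ratio ranges; non-overlapping by construction
AR_RANGES = {"round": (1.0, 1.3), "droplet": (1.4, 2.2), "spindle": (2.5, 6.0)}


@dataclass
class PopulationSpec:
    """Study conditions for one synthetic population.

    Defaults emulate a mixed culture of the three morphotypes: 100 cells per
    class, mean equivalent diameter 40 μm (SD 6), 5 % boundary noise.
    """

    n_round: int = 100
    n_droplet: int = 100
    n_spindle: int = 100
    size_mean: float = 40.0  # equivalent diameter, μm
    size_sd: float = 6.0
    boundary_noise: float = 0.05  # fractional radial perturbation amplitude
    ar_ranges: dict = field(default_factory=lambda: dict(AR_RANGES))
    image_size: tuple[int, int] | None = None  # auto when None
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_round, self.n_droplet, self.n_spindle) < 0:
            raise ValueError("class counts must be non-negative")
        if not 0 <= self.boundary_noise <= 0.3:
            raise ValueError("boundary_noise must be in [0, 0.3]")

    @property
    def counts(self) -> dict[str, int]:
        return {"round": self.n_round, "droplet": self.n_droplet,
                "spindle": self.n_spindle}


# ---------------------------------------------------------------------------
# boundary construction (in physical units, centred at origin, front at +x)
# ---------------------------------------------------------------------------

def _smooth_radial_noise(theta: np.ndarray, amplitude: float,
                         rng: np.random.Generator, n_modes: int = 6) -> np.ndarray:
    """Band-limited multiplicative radial perturbation, mean 1."""
    if amplitude == 0:
        return np.ones_like(theta)
    pert = np.zeros_like(theta)
    for m in range(2, 2 + n_modes):
        a, b = rng.normal(size=2)
        pert += a * np.cos(m * theta) + b * np.sin(m * theta)
    pert /= max(1e-12, np.abs(pert).max())
    return 1.0 + amplitude * pert


def _round_boundary(area: float, ar: float, rng: np.random.Generator,
                    noise: float, n_pts: int = 256) -> np.ndarray:
    """Noisy, mildly elongated disk (ellipse with AR close to 1)."""
    b = np.sqrt(area / (np.pi * ar))
    a = ar * b
    t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    r = np.hypot(x, y) * _smooth_radial_noise(t, noise, rng)
    ang = np.arctan2(y, x)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def _spindle_boundary(area: float, ar: float, rng: np.random.Generator,
                      noise: float, n_pts: int = 256, tip_power: float = 1.6) -> np.ndarray:
    """Elongated lens: ellipse sharpened at the poles (|sin|^p width profile)."""
    t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    a, b = 1.0, 1.0 / ar
    x = a * np.cos(t)
    y = b * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** tip_power
    r = np.hypot(x, y) * _smooth_radial_noise(t, noise, rng)
    ang = np.arctan2(y, x)
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return pts * np.sqrt(area / _poly_area(pts))


def _droplet_boundary(area: float, ar: float, rng: np.random.Generator,
                      noise: float, n_pts: int = 256,
                      front_exponent: float = 4.0,
                      tail_power: float = 0.6,
                      tail_fraction: float = 0.6) -> np.ndarray:
    """Teardrop: superellipse front (flat, wide) blended with a tapering tail.

    The front (x > 0) follows |x/Lf|^p + |y/b|^p = 1 with p = front_exponent,
    giving a flattened leading edge; the tail (x < 0) width decays as
    (1 − |x|/Lt)^tail_power, tapering to a blunt point.  Lf + Lt and b are
    set from the requested aspect ratio and area.
    """
    total_len = 2.0  # provisional; rescaled to the requested area afterwards
    Lt = tail_fraction * total_len
    Lf = total_len - Lt
    b = total_len / (2.0 * ar)
    n_half = n_pts // 2
    # half-width profile w(x): superellipse front, power-taper tail; the
    # boundary is the graph ±w(x), simple by construction
    x = np.concatenate(
        [np.linspace(-Lt, 0.0, n_half // 2, endpoint=False),
         np.linspace(0.0, Lf, n_half - n_half // 2)]
    )
    w = np.where(
        x >= 0,
        b * np.maximum(0.0, 1.0 - (x / Lf) ** front_exponent) ** (1.0 / front_exponent),
        b * np.maximum(0.0, 1.0 - (-x / Lt)) ** tail_power,
    )
    upper = np.column_stack([x, w])
    lower = np.column_stack([x[::-1], -w[::-1]])
    pts = _dedupe(np.vstack([upper, lower]))
    centre = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    r = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
    r = r * _smooth_radial_noise(ang, noise, rng)
    pts = centre + np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    pts = pts * np.sqrt(area / _poly_area(pts))
    return pts - pts.mean(axis=0)


def _poly_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return abs(0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _dedupe(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    return pts[keep]


_BUILDERS = {
    "round": _round_boundary,
    "droplet": _droplet_boundary,
    "spindle": _spindle_boundary,
}


def _sample_cell_boundary(cls: str, spec: PopulationSpec,
                          rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """One random archetype boundary (physical units) + its truth record."""
    lo, hi = spec.ar_ranges[cls]
    ar = rng.uniform(lo, hi)
    diameter = max(10.0, rng.normal(spec.size_mean, spec.size_sd))
    area = np.pi * (diameter / 2.0) ** 2
    pts = _BUILDERS[cls](area, ar, rng, spec.boundary_noise)
    angle = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(angle), np.sin(angle)
    pts = pts @ np.array([[c, -s], [s, c]]).T
    truth = {"class": cls, "target_ar": ar, "target_area": area,
             "orientation": angle}
    return pts, truth


def _rasterise(pts_px: np.ndarray, shape: tuple[int, int],
               label_img: np.ndarray, cell_id: int) -> int:
    """Fill polygon (x, y order, pixel units) into label_img; returns px count."""
    rr, cc = draw_polygon(pts_px[:, 1], pts_px[:, 0], shape=shape)
    free = label_img[rr, cc] == 0
    label_img[rr[free], cc[free]] = cell_id
    return int(free.sum())


def make_archetype_mask(
    cls: str,
    *,
    area: float = 1250.0,
    ar: float | None = None,
    boundary_noise: float = 0.0,
    pixel_size: float = 1.0,
    seed: int = 0,
    pad: int = 4,
    rotation: float | None = 0.0,
) -> tuple[LabelMask, dict]:
    """Rasterise one archetype cell as a single-cell label mask.

    Returns (mask, truth) where truth records the class, target aspect ratio
    and target area.  ``rotation=None`` draws a random orientation.
    """
    if cls not in ARCHETYPES:
        raise ValueError(f"unknown archetype {cls!r}; expected one of {ARCHETYPES}")
    rng = np.random.default_rng(seed)
    if ar is None:
        ar = float(np.mean(AR_RANGES[cls]))
    pts = _BUILDERS[cls](area, ar, rng, boundary_noise)
    if rotation is None:
        rotation = float(rng.uniform(0, 2 * np.pi))
    c, s = np.cos(rotation), np.sin(rotation)
    pts = pts @ np.array([[c, -s], [s, c]]).T
    pts_px = pts / pixel_size
    mins = pts_px.min(axis=0)
    pts_px = pts_px - mins + pad
    extent_px = np.ceil(pts_px.max(axis=0)).astype(int) + pad
    shape = (int(extent_px[1]) + 1, int(extent_px[0]) + 1)
    img = np.zeros(shape, dtype=np.int32)
    n_px = _rasterise(pts_px, shape, img, 1)
    if n_px < 20:
        raise ValueError("shape too small to rasterise (< 20 px); increase area "
                         "or decrease pixel_size")
    truth = {"cell_id": 1, "class": cls, "target_ar": float(ar),
             "target_area": float(area), "orientation": float(rotation)}
    return LabelMask(img, pixel_size), truth


def make_population(spec: PopulationSpec) -> tuple[LabelMask, pd.DataFrame]:
    """Place a mixed three-archetype population on one label image.

    Cells are dropped at random non-overlapping positions (bounding-disc
    test, bounded retries); the truth table records class, target aspect
    ratio and area per cell id.  Deterministic per seed.
    """
    total = sum(spec.counts.values())
    if total < 1:
        raise ValueError("population must contain at least one cell")
    rng = np.random.default_rng(spec.seed)

    cells = []
    for cls in ARCHETYPES:
        for _ in range(spec.counts[cls]):
            pts, truth = _sample_cell_boundary(cls, spec, rng)
            radius = np.linalg.norm(pts, axis=1).max()
            cells.append((pts, radius, truth))

    if spec.image_size is None:
        # size image so packing stays sparse (~5x summed bounding-disc area)
        disc_area = sum(np.pi * r**2 for _, r, _ in cells)
        side_um = np.sqrt(5.0 * disc_area)
        side_px = int(np.ceil(side_um / spec.pixel_size))
        shape = (side_px, side_px)
    else:
        shape = spec.image_size

    img = np.zeros(shape, dtype=np.int32)
    h_um = shape[0] * spec.pixel_size
    w_um = shape[1] * spec.pixel_size
    placed: list[tuple[np.ndarray, float]] = []
    truth_rows = []
    # place the largest cells first: greatly improves packing success
    order = np.argsort([-r for _, r, _ in cells], kind="stable")
    id_by_order = {}
    for rank, ci in enumerate(order):
        pts, radius, truth = cells[ci]
        margin = radius + 2 * spec.pixel_size
        if 2 * margin >= min(h_um, w_um):
            raise ValueError("image too small for the largest cell; enlarge image_size")
        ok = False
        for _ in range(2000):
            cx = rng.uniform(margin, w_um - margin)
            cy = rng.uniform(margin, h_um - margin)
            if all(np.hypot(cx - px, cy - py) > radius + pr + spec.pixel_size
                   for (px, py), pr in placed):
                ok = True
                break
        if not ok:
            raise ValueError(
                "could not place all cells without overlap; enlarge image_size"
            )
        placed.append(((cx, cy), radius))
        cell_id = rank + 1
        pts_px = (pts + np.array([cx, cy])) / spec.pixel_size
        _rasterise(pts_px, shape, img, cell_id)
        truth_rows.append({"cell_id": cell_id, **truth})
    truth_df = pd.DataFrame(truth_rows).sort_values("cell_id").reset_index(drop=True)
    return LabelMask(img, spec.pixel_size), truth_df


def make_elongation_dominated_features(n: int = 300, seed: int = 0) -> pd.DataFrame:
    """Feature table with a constructed covariance dominated by elongation.

    A latent elongation axis drives the aspect ratio almost perfectly and
    the other size-free descriptors only partially (each carries independent
    measurement noise); the symmetric ratio is nearly orthogonal.  Used to
    check that PCA attributes the leading component to the aspect ratio
    when elongation dominates the population variance.
    """
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)  # latent elongation
    mix = lambda w: w * e + np.sqrt(1 - w**2) * rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "roundness": np.clip(0.75 - 0.12 * mix(0.75), 0.05, 1.0),
            "extent": np.clip(0.7 - 0.08 * mix(0.7), 0.05, 1.0),
            "inscribed_circle_ratio": np.clip(0.6 - 0.1 * mix(0.7), 0.05, 1.0),
            "aspect_ratio": np.maximum(1.0, 2.5 + 1.1 * mix(0.97)),
            "symmetric_ratio": np.clip(0.12 + 0.05 * mix(0.1), 0.0, 0.99),
            "signature_peaks": np.maximum(0, np.round(3 + mix(0.3))),
        }
    )
    table.insert(0, "cell_id", np.arange(1, n + 1))
    return table


def make_fibre(waviness: float = 0.1, n_points: int = 200, *, length: float = 30.0,
               n_waves: float = 3.0, seed: int = 0, fibre_id: int = 0) -> FibreTrace:
    """Sinusoidally perturbed fibre polyline.

    ``waviness`` is the sine amplitude relative to the fibre length; the
    crimp ratio is strictly increasing in it.  A small seeded phase jitter
    varies individual fibres without changing the expectation.
    """
    if waviness < 0:
        raise ValueError("waviness must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length, n_points)
    phase = rng.uniform(0, 2 * np.pi)
    y = waviness * length * np.sin(2 * np.pi * n_waves * x / length + phase)
    y -= y[0]  # start on the chord for a clean end-to-end geometry
    return FibreTrace(np.column_stack([x, y]), fibre_id=fibre_id)


def make_nucleus(semi_axes: tuple[float, float, float] = (8.0, 5.0, 3.0),
                 dent_depth: float = 0.0,
                 voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.25),
                 seed: int = 0) -> NucleusMask3D:
    """Rasterised ellipsoid nucleus with an optional spherical surface dent.

    ``semi_axes`` = (ax, ay, az) in μm; ``voxel_size`` = (dz, dy, dx).
    With ``dent_depth`` 0 the analytic volume is (4/3)π·ax·ay·az and the
    height 2·az.  A dent (sphere subtracted at the +x pole, radius
    ``dent_depth``·ax) makes the shape non-convex.
    """
    ax, ay, az = semi_axes
    if min(ax, ay, az) <= 0:
        raise ValueError("semi-axes must be positive")
    dz, dy, dx = voxel_size
    pad = 2
    nx = int(np.ceil(2 * ax / dx)) + 2 * pad
    ny = int(np.ceil(2 * ay / dy)) + 2 * pad
    nz = int(np.ceil(2 * az / dz)) + 2 * pad
    z, y, x = np.meshgrid(
        (np.arange(nz) - nz / 2 + 0.5) * dz,
        (np.arange(ny) - ny / 2 + 0.5) * dy,
        (np.arange(nx) - nx / 2 + 0.5) * dx,
        indexing="ij",
    )
    vox = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0
    if dent_depth > 0:
        r_dent = dent_depth * ax
        vox &= (x - ax) ** 2 + y**2 + z**2 > r_dent**2
    return NucleusMask3D(vox, (dz, dy, dx))
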