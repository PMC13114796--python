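"""Shared fixtures: rasterised analytic shapes and random smooth blobs."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from morphocell.shape_descriptors import LabelMask, extract_contours


def rasterise_polygon(pts: np.ndarray, pad: int = 3) -> np.ndarray:
    """Binary image of a polygon given in (x, y) coordinates."""
    pts = np.asarray(pts, dtype=float)
    pts = pts - pts.min(axis=0) + pad
    shape = (int(np.ceil(pts[:, 1].max())) + pad + 1,
             int(np.ceil(pts[:, 0].max())) + pad + 1)
    img = np.zeros(shape, dtype=np.int32)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
    img[rr, cc] = 1
    return img


def single_contour(img: np.ndarray, pixel_size: float = 1.0):
    cs = extract_contours(LabelMask(img.astype(np.int32), pixel_size),
                          0.0, exclude_border=False)
    assert len(cs) == 1
    return cs[0]


def make_blob(seed: int, radius: float = 45.0) -> np.ndarray:
    """Random star-convex smooth blob (band-limited radial perturbation)."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = np.ones_like(th)
    for m in range(2, 7):
        a, b = rng.normal(size=2) * 0.25 / m
        r += a * np.cos(m * th) + b * np.sin(m * th)
    r = radius * np.clip(r, 0.3, None)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return rasterise_polygon(pts, pad=5)


@pytest.fixture(scope="session")
def disk_image() -> np.ndarray:
    img = np.zeros((220, 220), dtype=np.int32)
    rr, cc = draw_disk((110, 110), 100)
    img[rr, cc] = 1
    return img


@pytest.fixture(scope="session")
def ellipse_2to1_image() -> np.ndarray:
    yy, xx = np.mgrid[0:140, 0:200]
    return (((xx - 100) / 80.0) ** 2 + ((yy - 70) / 40.0) ** 2 <= 1).astype(np.int32)


@pytest.fixture(scope="session")
def small_population():
    """A 20-cells-per-class synthetic population with truth labels."""
    from morphocell.synthetic_data import PopulationSpec, make_population

    spec = PopulationSpec(n_round=20, n_droplet=20, n_spindle=20, seed=11)
    return make_population(spec)


@pytest.fixture(scope="session")
def small_population_features(small_population):
    from morphocell.shape_descriptors import featurize

    mask, truth = small_population
    feats = featurize(mask)
    return feats.merge(truth, on="cell_id")
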