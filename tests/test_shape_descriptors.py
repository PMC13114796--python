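"""Descriptor correctness: closed forms, pixel oracles, invariances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from morphocell.shape_descriptors import (
    DescriptorConfig,
    LabelMask,
    ShapeFeaturizer,
    aspect_ratio,
    boundary_signature,
    contour_from_polygon,
    extent,
    extract_contours,
    featurize,
    inscribed_circle_ratio,
    leading_edge_metrics,
    roundness,
    signature_peaks,
    symmetric_ratio,
    FEATURE_COLUMNS,
)

from conftest import make_blob, rasterise_polygon, single_contour


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

class TestExtractContours:
    def test_square_area(self):
        img = np.zeros((60, 60), dtype=np.int32)
        img[10:50, 10:50] = 1
        cs = extract_contours(LabelMask(img), 0.0, exclude_border=False)
        assert len(cs) == 1
        assert cs[0].area == pytest.approx(1600, rel=0.05)
        assert cs[0].polygon_area == pytest.approx(1600, rel=0.05)

    def test_empty_mask(self):
        assert extract_contours(LabelMask(np.zeros((30, 30), dtype=np.int32))) == []

    def test_touching_cells_disjoint(self):
        img = np.zeros((60, 90), dtype=np.int32)
        img[10:50, 10:45] = 1
        img[10:50, 45:80] = 2
        cs = extract_contours(LabelMask(img), 0.0, exclude_border=False)
        assert {c.cell_id for c in cs} == {1, 2}
        # interiors disjoint: pixel-membership oracle
        inter = cs[0].polygon.buffer(-0.6).intersection(cs[1].polygon.buffer(-0.6))
        assert inter.area == pytest.approx(0.0, abs=1e-6)
        # each pixel belongs to the polygon of its own label
        for c in cs:
            pts = c.region_points()
            sample = pts[:: max(1, len(pts) // 50)]
            from shapely.geometry import Point

            assert all(c.polygon.distance(Point(*p)) < 1.0 for p in sample)

    def test_border_cells_dropped_by_default(self):
        img = np.zeros((40, 40), dtype=np.int32)
        img[0:15, 5:20] = 1  # touches top border
        assert extract_contours(LabelMask(img), 0.0) == []
        assert len(extract_contours(LabelMask(img), 0.0, exclude_border=False)) == 1

    def test_min_area_filter(self):
        img = np.zeros((60, 60), dtype=np.int32)
        img[5:10, 5:10] = 1  # 25 px
        img[20:50, 20:50] = 2  # 900 px
        cs = extract_contours(LabelMask(img), min_area=100.0, exclude_border=False)
        assert [c.cell_id for c in cs] == [2]

    def test_holes_filled_and_flagged(self):
        img = np.zeros((60, 60), dtype=np.int32)
        img[10:50, 10:50] = 1
        img[25:35, 25:35] = 0  # hole
        cs = extract_contours(LabelMask(img), 0.0, exclude_border=False)
        assert cs[0].had_holes
        assert cs[0].area == pytest.approx(1600, rel=0.05)


# ---------------------------------------------------------------------------
# closed-form descriptor values
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_roundness_circle_polygon(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        ct = contour_from_polygon(np.column_stack([60 + 50 * np.cos(th),
                                                   60 + 50 * np.sin(th)]))
        assert roundness(ct) == pytest.approx(1.0, abs=1e-3)

    def test_roundness_rectangle(self):
        ct = contour_from_polygon(np.array([[0, 0], [60, 0], [60, 30], [0, 30]], float))
        assert roundness(ct) == pytest.approx(8 * np.pi / 36, rel=1e-6)

    def test_roundness_raster_disk(self, disk_image):
        assert roundness(single_contour(disk_image)) == pytest.approx(1.0, abs=0.02)

    def test_extent_rectangle_and_disk(self, disk_image):
        img = np.zeros((60, 100), dtype=np.int32)
        img[10:50, 10:90] = 1
        assert extent(single_contour(img)) == pytest.approx(1.0, rel=0.02)
        assert extent(single_contour(disk_image)) == pytest.approx(np.pi / 4, rel=0.02)

    def test_extent_rotated_square(self):
        s = 140.0
        pts = np.array([[0, -s], [s, 0], [0, s], [-s, 0]]) / np.sqrt(2)
        img = rasterise_polygon(pts + 160)
        assert extent(single_contour(img)) == pytest.approx(0.5, rel=0.02)

    def test_inscribed_circle_ratio(self, disk_image, ellipse_2to1_image):
        assert inscribed_circle_ratio(single_contour(disk_image)) == pytest.approx(1.0, rel=0.03)
        assert inscribed_circle_ratio(single_contour(ellipse_2to1_image)) == pytest.approx(0.5, rel=0.03)
        sq = np.zeros((80, 80), dtype=np.int32)
        sq[10:70, 10:70] = 1
        assert inscribed_circle_ratio(single_contour(sq)) == pytest.approx(np.pi / 4, rel=0.03)

    def test_aspect_ratio_circle_ellipse_bar(self, disk_image, ellipse_2to1_image):
        assert aspect_ratio(single_contour(disk_image)) == pytest.approx(1.0, rel=0.02)
        assert aspect_ratio(single_contour(ellipse_2to1_image)) == pytest.approx(2.0, rel=0.02)
        bar = np.zeros((60, 240), dtype=np.int32)
        bar[20:40, 20:220] = 1
        assert aspect_ratio(single_contour(bar)) == pytest.approx(10.0, rel=0.05)

    def test_aspect_ratio_rotation_invariant(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        base = np.column_stack([60 * np.cos(th), 30 * np.sin(th)])
        a0 = aspect_ratio(single_contour(rasterise_polygon(base + 80)))
        rot = np.radians(30)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        a30 = aspect_ratio(single_contour(rasterise_polygon(base @ R.T + 90)))
        assert a30 == pytest.approx(a0, rel=0.02)

    def test_symmetric_ratio_ellipse_near_zero(self, ellipse_2to1_image):
        assert symmetric_ratio(single_contour(ellipse_2to1_image)) == pytest.approx(0.0, abs=0.03)

    def test_symmetric_ratio_teardrop_above_ellipse(self):
        from morphocell.synthetic_data import make_archetype_mask

        drop, _ = make_archetype_mask("droplet", seed=0)
        ct_d = extract_contours(drop, 0.0, exclude_border=False)[0]
        ar = aspect_ratio(ct_d)
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ell = rasterise_polygon(np.column_stack([40 * ar * np.cos(th), 40 * np.sin(th)]) + 120)
        assert symmetric_ratio(ct_d) > symmetric_ratio(single_contour(ell)) + 0.05

    def test_symmetric_ratio_raw_doubles_default(self, ellipse_2to1_image):
        from morphocell.synthetic_data import make_archetype_mask

        drop, _ = make_archetype_mask("droplet", seed=0)
        ct = extract_contours(drop, 0.0, exclude_border=False)[0]
        assert symmetric_ratio(ct, raw=True) == pytest.approx(
            2 * symmetric_ratio(ct), rel=1e-9
        )

    @pytest.mark.parametrize(
        "shape,expected",
        [("circle", 0), ("ellipse", 2), ("star5", 5)],
    )
    def test_signature_peaks(self, shape, expected, disk_image, ellipse_2to1_image):
        if shape == "circle":
            ct = single_contour(disk_image)
        elif shape == "ellipse":
            ct = single_contour(ellipse_2to1_image)
        else:
            t = np.arange(10) * np.pi / 5 - np.pi / 2
            r = np.where(np.arange(10) % 2 == 0, 60, 25)
            ct = single_contour(
                rasterise_polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]) + 70)
            )
        assert signature_peaks(ct) == expected


# ---------------------------------------------------------------------------
# leading edge
# ---------------------------------------------------------------------------

class TestLeadingEdge:
    def test_disk_full_boundary(self, disk_image):
        length, frac = leading_edge_metrics(single_contour(disk_image))
        assert frac == pytest.approx(1.0)
        assert length == pytest.approx(single_contour(disk_image).perimeter)

    def test_droplet_front_beats_spindle(self):
        from morphocell.synthetic_data import make_archetype_mask

        fracs = {}
        for cls in ("droplet", "spindle"):
            mask, _ = make_archetype_mask(cls, seed=0)
            ct = extract_contours(mask, 0.0, exclude_border=False)[0]
            fracs[cls] = leading_edge_metrics(ct)[1]
        assert fracs["droplet"] > fracs["spindle"]

    def test_no_qualifying_arc_returns_zero(self, disk_image):
        # a disk's curvature 1/r exceeds a threshold of 0.5/r everywhere
        ct = single_contour(disk_image)
        length, frac = leading_edge_metrics(ct, curvature_factor=0.5)
        assert (length, frac) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# independent pixel oracles on random blobs
# ---------------------------------------------------------------------------

def _oracle_descriptors(img: np.ndarray) -> dict[str, float]:
    """Brute-force pixel implementations: pixel counting, Crofton perimeter,
    exhaustive distance search, explicit moment sums, raster fold-XOR and a
    dense per-boundary-pixel angular signature."""
    from skimage.measure import perimeter_crofton

    reg = img.astype(bool)
    A = float(reg.sum())
    P = float(perimeter_crofton(reg, directions=4))
    rows, cols = np.nonzero(reg)
    bbox = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)

    er = ndimage.binary_erosion(reg)
    brows, bcols = np.nonzero(reg & ~er)
    outside = ~reg
    orows, ocols = np.nonzero(outside)
    # exhaustive max-min distance: interior pixels to nearest background pixel
    d2 = ((rows[:, None] - orows[None]) ** 2 + (cols[:, None] - ocols[None]) ** 2)
    rmax = np.sqrt(d2.min(axis=1).max())

    x = cols - cols.mean()
    y = rows - rows.mean()
    cxx = (x * x).mean() + 1 / 12
    cyy = (y * y).mean() + 1 / 12
    cxy = (x * y).mean()
    tr, det = cxx + cyy, cxx * cyy - cxy**2
    l1 = tr / 2 + np.sqrt(tr**2 / 4 - det)
    l2 = tr / 2 - np.sqrt(tr**2 / 4 - det)
    ar = float(np.sqrt(l1 / l2))

    ang = 0.5 * np.arctan2(2 * cxy, cxx - cyy)
    rot = ndimage.rotate(reg.astype(np.uint8), np.degrees(ang), order=0, reshape=True)
    r2, c2 = np.nonzero(rot)
    ccol = c2.mean()
    flip = np.zeros_like(rot)
    newc = np.round(2 * ccol - c2).astype(int)
    ok = (newc >= 0) & (newc < rot.shape[1])
    flip[r2[ok], newc[ok]] = 1
    sym = float(np.logical_xor(rot > 0, flip > 0).sum() / (2 * rot.sum()))

    return {
        "roundness": 4 * np.pi * A / P**2,
        "extent": A / bbox,
        "inscribed_circle_ratio": np.pi * rmax**2 / A,
        "aspect_ratio": ar,
        "symmetric_ratio": sym,
    }


def _oracle_signature_peaks(img: np.ndarray, n_bins=360, smooth_deg=5.0,
                            prominence=0.05, flat_tol=0.02) -> int:
    """Dense angular signature from boundary pixels, loop-based peak count."""
    reg = img.astype(bool)
    er = ndimage.binary_erosion(reg)
    brows, bcols = np.nonzero(reg & ~er)
    rows, cols = np.nonzero(reg)
    cy, cx = rows.mean(), cols.mean()
    ang = np.arctan2(brows - cy, bcols - cx) % (2 * np.pi)
    rad = np.hypot(brows - cy, bcols - cx)
    bins = (ang / (2 * np.pi) * n_bins).astype(int) % n_bins
    sig = np.zeros(n_bins)
    for b in range(n_bins):
        sel = rad[bins == b]
        sig[b] = sel.max() if sel.size else np.nan
    # fill empty bins by circular interpolation
    if np.isnan(sig).any():
        idx = np.arange(n_bins)
        good = ~np.isnan(sig)
        sig = np.interp(idx, idx[good], sig[good], period=n_bins)
    window = max(1, int(round(smooth_deg / (360 / n_bins))))
    sm = np.array([
        np.mean([sig[(i + j) % n_bins] for j in range(-(window // 2), window // 2 + 1)])
        for i in range(n_bins)
    ])
    rng = sm.max() - sm.min()
    if rng < flat_tol * sm.mean():
        return 0
    def side_min(i: int, step: int) -> float:
        # walk away from the peak until a higher point; track the minimum
        lowest = sm[i]
        for j in range(1, n_bins):
            v = sm[(i + step * j) % n_bins]
            if v > sm[i]:
                break
            lowest = min(lowest, v)
        return lowest

    peaks = []
    for i in range(n_bins):
        prev, nxt = sm[(i - 1) % n_bins], sm[(i + 1) % n_bins]
        if sm[i] > prev and sm[i] >= nxt:
            prom = sm[i] - max(side_min(i, -1), side_min(i, +1))
            if prom >= prominence * rng:
                peaks.append(i)
    # merge circularly-close maxima
    min_dist = max(window, n_bins // 36)
    if not peaks:
        return 0
    peaks = np.asarray(sorted(peaks))
    gaps = np.diff(peaks, append=peaks[0] + n_bins)
    return max(1, int((gaps >= min_dist).sum()))


class TestPixelOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_descriptors_match_oracle(self, seed):
        img = make_blob(seed)
        ct = single_contour(img)
        oracle = _oracle_descriptors(img)
        impl = {
            "roundness": roundness(ct),
            "extent": extent(ct),
            "inscribed_circle_ratio": inscribed_circle_ratio(ct),
            "aspect_ratio": aspect_ratio(ct),
            "symmetric_ratio": symmetric_ratio(ct),
        }
        for key, o in oracle.items():
            tol = 0.02 if key in ("roundness", "extent", "aspect_ratio") else 0.03
            assert impl[key] == pytest.approx(o, rel=tol, abs=0.01), key

    @pytest.mark.parametrize("seed", range(10))
    def test_signature_peaks_match_oracle(self, seed):
        img = make_blob(seed)
        ct = single_contour(img)
        assert signature_peaks(ct) == _oracle_signature_peaks(img)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

class TestInvariances:
    @pytest.mark.parametrize("angle", [17.0, 45.0, 101.0])
    def test_rotation_invariance(self, angle):
        img = make_blob(3)
        ct0 = single_contour(img)
        rot = ndimage.rotate(img.astype(np.uint8), angle, order=0, reshape=True)
        ct1 = single_contour(np.pad(rot, 3))
        for fn in (roundness, aspect_ratio, inscribed_circle_ratio):
            assert fn(ct1) == pytest.approx(fn(ct0), rel=0.03)
        assert symmetric_ratio(ct1) == pytest.approx(symmetric_ratio(ct0), abs=0.02)

    def test_scale_invariance_and_dimensioned_scaling(self):
        img = make_blob(5)
        ct0 = single_contour(img)
        up = img.repeat(2, axis=0).repeat(2, axis=1)
        ct1 = single_contour(up)
        for fn in (roundness, extent, aspect_ratio, inscribed_circle_ratio):
            assert fn(ct1) == pytest.approx(fn(ct0), rel=0.02)
        assert ct1.area == pytest.approx(4 * ct0.area, rel=0.02)
        assert ct1.perimeter == pytest.approx(2 * ct0.perimeter, rel=0.02)

    def test_pixel_size_scales_dimensioned_quantities(self, disk_image):
        ct1 = single_contour(disk_image, pixel_size=1.0)
        ct2 = single_contour(disk_image, pixel_size=0.5)
        assert ct2.area == pytest.approx(ct1.area / 4)
        assert ct2.perimeter == pytest.approx(ct1.perimeter / 2)
        assert roundness(ct2) == pytest.approx(roundness(ct1), rel=1e-9)


# ---------------------------------------------------------------------------
# batch featurization
# ---------------------------------------------------------------------------

class TestFeaturize:
    def test_population_no_nans_sorted(self, small_population):
        mask, truth = small_population
        table = featurize(mask)
        assert len(table) == len(truth)
        assert not table[FEATURE_COLUMNS].isna().any().any()
        assert (table.cell_id.values == np.sort(table.cell_id.values)).all()

    def test_empty_mask_gives_empty_table_with_header(self):
        table = featurize(LabelMask(np.zeros((50, 50), dtype=np.int32)))
        assert table.empty
        assert list(table.columns) == FEATURE_COLUMNS

    def test_border_only_mask_empty(self):
        img = np.zeros((40, 40), dtype=np.int32)
        img[0:20, 10:30] = 1
        assert featurize(LabelMask(img)).empty

    def test_archetype_ordering(self, small_population_features):
        means = small_population_features.groupby("class")[
            ["aspect_ratio", "roundness"]
        ].mean()
        assert (
            means.loc["spindle", "aspect_ratio"]
            > means.loc["droplet", "aspect_ratio"]
            > means.loc["round", "aspect_ratio"]
        )
        assert (
            means.loc["round", "roundness"]
            > means.loc["droplet", "roundness"]
            > means.loc["spindle", "roundness"]
        )

    def test_leading_edge_fraction_consistency(self, small_population):
        mask, _ = small_population
        t = featurize(mask)
        good = t[t.leading_edge_length > 0]
        np.testing.assert_allclose(
            good.leading_edge_fraction, good.leading_edge_length / good.perimeter,
            rtol=1e-9,
        )

    def test_sklearn_transformer_protocol(self, small_population):
        mask, truth = small_population
        est = ShapeFeaturizer(min_area=20.0)
        assert est.get_params()["min_area"] == 20.0
        out = est.fit_transform([mask.pixels])
        assert "mask_index" in out.columns
        assert len(out) == len(truth)
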