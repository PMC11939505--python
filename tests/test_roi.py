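"""ROI rasterization against an independent oracle, measurement, transfer,
persistence."""

import numpy as np
import pytest
import shapely

from socketry.roi import (
    EllipseRoi,
    PolygonRoi,
    RoiError,
    RoiSet,
    SchemaError,
    is_simple_polygon,
    load_roiset,
    measure,
    rasterize,
    save_roiset,
    transfer_roiset,
)
from socketry.volume_io import VoxelVolume


def make_volume(data, spacing=(0.2, 0.2, 0.2), **kw):
    return VoxelVolume(data=np.asarray(data), spacing=spacing, **kw)


def random_star_polygon(rng, shape, n_vertices):
    """Random star-shaped (hence simple) polygon inside the slice."""
    rows, cols = shape
    cx = rng.uniform(0.3, 0.7) * cols
    cy = rng.uniform(0.3, 0.7) * rows
    # jittered evenly spaced angles keep every angular wedge below pi,
    # which guarantees the star-shaped chain is simple
    angles = 2 * np.pi * (np.arange(n_vertices) + rng.uniform(0.3, 0.7, n_vertices)) / n_vertices
    radii = rng.uniform(0.1, 0.45) * min(rows, cols) * rng.uniform(0.3, 1.0, n_vertices)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return PolygonRoi(slice_index=0, vertices=list(zip(xs, ys)))


def brute_force_polygon_mask(vertices, shape):
    """Oracle: per-pixel-center containment via shapely (covers includes
    the boundary, matching the boundary-inside tie-break)."""
    poly = shapely.Polygon(vertices)
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            mask[r, c] = shapely.covers(poly, shapely.Point(c + 0.5, r + 0.5))
    return mask


def brute_force_ellipse_mask(roi, shape):
    rows, cols = shape
    cx, cy = roi.center
    a, b = roi.semi_axes
    mask = np.zeros(shape, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            x, y = c + 0.5, r + 0.5
            mask[r, c] = (x - cx) ** 2 / a**2 + (y - cy) ** 2 / b**2 <= 1.0
    return mask


class TestRasterize:
    def test_axis_aligned_rectangle_exact_count(self):
        roi = PolygonRoi(0, [(0, 0), (10, 0), (10, 10), (0, 10)])
        mask = rasterize(roi, (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all() and not mask[10:, :].any() and not mask[:, 10:].any()

    def test_tiny_ellipse_hits_single_pixel(self):
        roi = EllipseRoi(0, center=(5.5, 7.5), semi_axes=(0.4, 0.4))
        mask = rasterize(roi, (16, 16))
        assert mask.sum() == 1
        assert mask[7, 5]

    def test_degenerate_collinear_triangle_is_empty(self):
        roi = PolygonRoi(0, [(1, 1), (5, 1), (9, 1)])
        # the chain runs along y=1; no pixel center (y = r+0.5) lies on it
        assert rasterize(roi, (12, 12)).sum() == 0

    def test_self_intersecting_polygon_rejected(self):
        bowtie = PolygonRoi(0, [(0, 0), (10, 10), (10, 0), (0, 10)])
        assert not is_simple_polygon(bowtie.vertices)
        with pytest.raises(RoiError, match="self-intersecting"):
            rasterize(bowtie, (12, 12))

    def test_agrees_with_brute_force_on_random_polygons(self, rng):
        shape = (24, 28)
        for _ in range(100):
            roi = random_star_polygon(rng, shape, int(rng.integers(3, 12)))
            np.testing.assert_array_equal(
                rasterize(roi, shape), brute_force_polygon_mask(roi.vertices, shape)
            )

    def test_agrees_with_brute_force_on_random_ellipses(self, rng):
        shape = (24, 28)
        for _ in range(100):
            roi = EllipseRoi(
                0,
                center=(rng.uniform(4, 24), rng.uniform(4, 20)),
                semi_axes=(rng.uniform(0.3, 8), rng.uniform(0.3, 8)),
            )
            np.testing.assert_array_equal(
                rasterize(roi, shape), brute_force_ellipse_mask(roi, shape)
            )


class TestMeasure:
    def test_rectangle_area_mm2(self):
        roi = PolygonRoi(0, [(0, 0), (10, 0), (10, 10), (0, 10)])
        v = make_volume(np.full((1, 20, 20), 50, np.uint8), spacing=(0.2, 0.2, 0.2))
        m = measure(roi, v)
        assert m.pixel_count == 100
        assert m.area_mm2 == pytest.approx(4.0)

    def test_mean_gray_of_constant_slice(self):
        roi = EllipseRoi(0, center=(8, 8), semi_axes=(3, 2))
        v = make_volume(np.full((1, 16, 16), 17, np.uint8))
        assert measure(roi, v).mean_gray == 17.0

    def test_deterministic(self, rng):
        roi = random_star_polygon(rng, (16, 16), 7)
        v = make_volume(rng.integers(0, 256, (1, 16, 16)).astype(np.uint8))
        assert measure(roi, v) == measure(roi, v)

    def test_empty_roi_errors(self):
        roi = EllipseRoi(0, center=(5.0, 5.0), semi_axes=(0.2, 0.2))  # between centers
        v = make_volume(np.zeros((1, 12, 12), np.uint8))
        with pytest.raises(RoiError, match="covers no pixels"):
            measure(roi, v)

    def test_area_invariant_under_integer_translation(self, rng):
        shape = (40, 40)
        v = make_volume(np.zeros((1, *shape), np.uint8))
        roi = random_star_polygon(rng, (20, 20), 9)
        base = measure(roi.translated(8, 8), v).pixel_count
        for dx, dy in [(0, 0), (3, 0), (0, 5), (7, 6)]:
            assert measure(roi.translated(8 + dx, 8 + dy), v).pixel_count == base

    def test_nested_rois_on_radial_phantom_monotone_mean(self):
        # gray decreases with radius; growing the ROI can only lower the mean
        rr, cc = np.mgrid[0:40, 0:40]
        radial = np.clip(220 - 4 * np.hypot(rr - 19.5, cc - 19.5), 0, 255).astype(np.uint8)
        v = make_volume(radial[np.newaxis])
        means = [
            measure(EllipseRoi(0, center=(20, 20), semi_axes=(a, a)), v).mean_gray
            for a in (2, 5, 9, 14, 18)
        ]
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))


class TestTransfer:
    def _roiset(self):
        return RoiSet(
            volume_id="v",
            timepoint="t1",
            rois=(
                PolygonRoi(0, [(2, 2), (8, 2), (8, 9), (2, 9)]),
                EllipseRoi(0, center=(12, 5), semi_axes=(2, 1)),
            ),
        )

    def test_identical_landmarks_zero_offset(self):
        lm = PolygonRoi(0, [(0, 0), (4, 0), (2, 3)], label="other")
        out = transfer_roiset(self._roiset(), lm, lm)
        assert out == self._roiset()

    def test_offset_applied_to_every_vertex(self):
        lm1 = PolygonRoi(0, [(0, 0), (4, 0), (2, 3)], label="other")
        lm2 = PolygonRoi(0, [(3, -2), (7, -2), (5, 1)], label="other")
        out = transfer_roiset(self._roiset(), lm1, lm2)
        poly = out.rois[0]
        assert poly.vertices[0] == (5.0, 0.0)
        assert out.rois[1].center == (15.0, 3.0)

    def test_transfer_round_trip(self, rng):
        lm1 = PolygonRoi(0, [(0, 0), (4, 1), (2, 3)], label="other")
        lm2 = PolygonRoi(0, [(3.7, -2.1), (7.7, -1.1), (5.7, 0.9)], label="other")
        back = transfer_roiset(transfer_roiset(self._roiset(), lm1, lm2), lm2, lm1)
        for a, b in zip(back.rois, self._roiset().rois):
            if isinstance(a, PolygonRoi):
                np.testing.assert_allclose(a.vertices, b.vertices, atol=1e-9)
            else:
                np.testing.assert_allclose(a.center, b.center, atol=1e-9)

    def test_landmark_slice_mismatch_errors(self):
        lm1 = PolygonRoi(0, [(0, 0), (4, 0), (2, 3)], label="other")
        lm2 = PolygonRoi(3, [(0, 0), (4, 0), (2, 3)], label="other")
        with pytest.raises(RoiError, match="landmark"):
            transfer_roiset(self._roiset(), lm1, lm2)


class TestPersistence:
    def test_round_trip(self, tmp_path, rng):
        rois = []
        for i in range(25):
            rois.append(random_star_polygon(rng, (30, 30), 8).translated(0, 0))
            rois[-1] = PolygonRoi(i, rois[-1].vertices)  # one per slice
            rois.append(EllipseRoi(i, center=(20, 10), semi_axes=(3, 2)))
        rs = RoiSet(volume_id="vol-7", timepoint="t2", rois=tuple(rois))
        save_roiset(rs, tmp_path / "rois.json")
        assert load_roiset(tmp_path / "rois.json") == rs

    def test_empty_set_round_trip(self, tmp_path):
        rs = RoiSet(volume_id="v", timepoint="t1", rois=())
        save_roiset(rs, tmp_path / "empty.json")
        assert load_roiset(tmp_path / "empty.json") == rs

    def test_missing_field_names_offender(self, tmp_path):
        doc = (
            '{"schema_version": 1, "volume_id": "v", "timepoint": "t1", '
            '"rois": [{"type": "polygon", "label": "alveolus", "vertices": [[0,0],[1,0],[0,1]]}]}'
        )
        (tmp_path / "bad.json").write_text(doc)
        with pytest.raises(SchemaError, match="slice_index"):
            load_roiset(tmp_path / "bad.json")

    def test_duplicate_label_per_slice_rejected(self):
        with pytest.raises(RoiError, match="duplicate"):
            RoiSet(
                volume_id="v",
                timepoint="t1",
                rois=(
                    PolygonRoi(0, [(0, 0), (4, 0), (2, 3)]),
                    PolygonRoi(0, [(1, 1), (5, 1), (3, 4)]),
                ),
            )


def test_subsampled_keeps_even_slices_and_renumbers():
    rois = tuple(PolygonRoi(i, [(0, 0), (4, 0), (2, 3)]) for i in range(7))
    rs = RoiSet(volume_id="v", timepoint="t1", rois=rois)
    out = rs.subsampled(2)
    assert [r.slice_index for r in out.rois] == [0, 1, 2, 3]
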