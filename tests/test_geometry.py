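"""Window bookkeeping, stitching, centroid extraction, rasterisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lithospat as ls
from lithospat.geometry import read_tile_offsets


class TestObservationWindow:
    def test_area_counts_valid_pixels_only(self):
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        w = ls.ObservationWindow(10, 10, 2.0, valid_mask=mask)
        assert w.area_um2 == pytest.approx(50 * 4.0)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            ls.ObservationWindow(0, 10, 1.0)
        with pytest.raises(ValueError):
            ls.ObservationWindow(10, 10, -1.0)
        with pytest.raises(ValueError):
            ls.ObservationWindow(10, 10, 1.0, valid_mask=np.zeros((10, 10), bool))

    def test_contains_respects_valid_mask(self):
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        w = ls.ObservationWindow(4, 4, 1.0, valid_mask=mask)
        assert not w.contains(0.5, 0.5)[0]
        assert w.contains(1.5, 0.5)[0]
        assert not w.contains(4.5, 1.0)[0]  # outside rectangle

    def test_pixel_um_round_trip(self, rng):
        w = ls.ObservationWindow(64, 48, 0.07)
        x = rng.uniform(0, w.width_um, 200)
        y = rng.uniform(0, w.height_um, 200)
        row, col = w.pixel_of(x, y)
        cx, cy = (col + 0.5) * w.pixel_size_um, (row + 0.5) * w.pixel_size_um
        assert np.all(np.abs(cx - x) < w.pixel_size_um)
        assert np.all(np.abs(cy - y) < w.pixel_size_um)


class TestStitchTiles:
    def test_single_tile_identity(self):
        vals = np.arange(12.0).reshape(3, 4)
        canvas = ls.ObservationWindow(4, 3, 1.0)
        pano = ls.stitch_tiles([ls.RasterTile(vals, 0, 0)], canvas, ["Fe"])
        np.testing.assert_array_equal(pano.values[0], vals)
        assert pano.window.valid_mask is None  # fully covered

    def test_disjoint_tiles_union(self):
        a = ls.RasterTile(np.full((4, 4), 1.0), 0, 0)
        b = ls.RasterTile(np.full((4, 4), 2.0), 4, 0)
        canvas = ls.ObservationWindow(8, 4, 1.0)
        pano = ls.stitch_tiles([a, b], canvas, ["Fe"])
        np.testing.assert_array_equal(pano.values[0, :, :4], 1.0)
        np.testing.assert_array_equal(pano.values[0, :, 4:], 2.0)
        assert pano.window.n_valid == 32

    @pytest.mark.parametrize("rule,expected", [("last", 2.0), ("mean", 1.5),
                                               ("first", 1.0)])
    def test_overlap_rules_match_per_pixel_composite(self, rule, expected):
        # oracle: tiles overlap on column 3 only; composite hand-computed
        a = ls.RasterTile(np.full((4, 4), 1.0), 0, 0)
        b = ls.RasterTile(np.full((4, 4), 2.0), 3, 0)
        canvas = ls.ObservationWindow(7, 4, 1.0)
        pano = ls.stitch_tiles([a, b], canvas, ["Fe"], overlap_rule=rule)
        np.testing.assert_allclose(pano.values[0, :, 3], expected)
        np.testing.assert_allclose(pano.values[0, :, :3], 1.0)
        np.testing.assert_allclose(pano.values[0, :, 4:], 2.0)

    def test_uncovered_pixels_invalid(self):
        tile = ls.RasterTile(np.ones((2, 2)), 0, 0)
        canvas = ls.ObservationWindow(4, 4, 1.0)
        pano = ls.stitch_tiles([tile], canvas, ["Fe"])
        assert pano.window.n_valid == 4
        assert np.isnan(pano.values[0, 3, 3])

    def test_restitching_panorama_is_idempotent(self):
        a = ls.RasterTile(np.arange(16.0).reshape(4, 4), 1, 1)
        canvas = ls.ObservationWindow(6, 6, 1.0)
        pano = ls.stitch_tiles([a], canvas, ["Fe"])
        again = ls.stitch_tiles(
            [ls.RasterTile(np.nan_to_num(pano.values, nan=np.nan), 0, 0)],
            pano.window, ["Fe"])
        m = pano.window.full_mask()
        np.testing.assert_array_equal(again.values[0][m], pano.values[0][m])
        np.testing.assert_array_equal(again.window.full_mask(), m)

    def test_errors_name_offending_tile(self):
        big = ls.RasterTile(np.ones((5, 5)), 2, 2, name="t7")
        canvas = ls.ObservationWindow(6, 6, 1.0)
        with pytest.raises(ValueError, match="t7"):
            ls.stitch_tiles([big], canvas, ["Fe"])
        with pytest.raises(ValueError, match="channels"):
            ls.stitch_tiles([ls.RasterTile(np.ones((2, 2, 2)), 0, 0)],
                            canvas, ["Fe"])


class TestMaskToCentroids:
    def _mask(self, labels, classes=None):
        labels = np.asarray(labels)
        w = ls.ObservationWindow(labels.shape[1], labels.shape[0], 1.0)
        ids = [int(i) for i in np.unique(labels) if i > 0]
        return ls.FeatureMask(labels, classes or {i: "cell" for i in ids}, w)

    def test_square_feature_pixel_center_convention(self):
        labels = np.zeros((4, 4), int)
        labels[0:2, 0:2] = 1
        pat = ls.mask_to_centroids(self._mask(labels))
        np.testing.assert_allclose(pat.points, [[1.0, 1.0]])

    def test_empty_mask(self):
        pat = ls.mask_to_centroids(self._mask(np.zeros((4, 4), int)))
        assert pat.n == 0

    def test_l_shape_mean_of_pixel_centers(self):
        labels = np.zeros((4, 4), int)
        labels[0, 0] = labels[0, 1] = labels[1, 0] = 1
        pat = ls.mask_to_centroids(self._mask(labels))
        np.testing.assert_allclose(pat.points, [[5 / 6, 5 / 6]])

    def test_class_filter(self):
        labels = np.zeros((4, 8), int)
        labels[0, 0], labels[0, 4] = 1, 2
        mask = self._mask(labels, {1: "cell", 2: "fungal"})
        assert ls.mask_to_centroids(mask, "cell").n == 1
        assert ls.mask_to_centroids(mask, "fungal").n == 1
        assert ls.mask_to_centroids(mask).n == 2

    def test_isolated_single_pixels_recover_seeded_centers(self, rng):
        # property: single-pixel features sit exactly at pixel centres
        labels = np.zeros((32, 32), int)
        rows = rng.choice(32, 10, replace=False)
        cols = rng.choice(32, 10, replace=False)
        for k, (r, c) in enumerate(zip(rows, cols), start=1):
            labels[r, c] = k
        pat = ls.mask_to_centroids(self._mask(labels))
        got = {(x, y) for x, y in pat.points}
        want = {(c + 0.5, r + 0.5) for r, c in zip(rows, cols)}
        assert got == want


class TestRasterizePoints:
    def test_counts_and_coincidence(self):
        w = ls.ObservationWindow(4, 4, 1.0)
        pts = np.array([[0.5, 0.5], [0.6, 0.6], [3.5, 3.5]])
        counts = ls.rasterize_points(ls.CellPattern(pts, w))
        assert counts.sum() == 3
        assert counts[0, 0] == 2
        assert counts[3, 3] == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 300))
    def test_sum_equals_n_for_any_pattern(self, seed, n):
        w = ls.ObservationWindow(16, 16, 0.5)
        r = np.random.default_rng(seed)
        pts = np.column_stack([r.uniform(0, 8, n), r.uniform(0, 8, n)])
        assert ls.rasterize_points(ls.CellPattern(pts, w)).sum() == n

    def test_point_outside_raises_with_offenders(self):
        w = ls.ObservationWindow(4, 4, 1.0)
        pat = ls.CellPattern(np.array([[0.5, 0.5]]), w)
        other = ls.ObservationWindow(2, 2, 0.1)
        with pytest.raises(ValueError, match="outside"):
            ls.rasterize_points(pat, other)


class TestIO:
    def test_element_map_tiff_round_trip(self, tmp_path, small_map):
        p = tmp_path / "map.tif"
        small_map.to_tiff(p)
        back = ls.ElementMap.from_tiff(p)
        assert back.channels == small_map.channels
        np.testing.assert_allclose(back.values, small_map.values, rtol=1e-6)
        assert back.window.pixel_size_um == small_map.window.pixel_size_um

    def test_cell_pattern_csv_round_trip(self, tmp_path):
        w = ls.ObservationWindow(10, 10, 1.0)
        pat = ls.CellPattern(np.array([[1.5, 2.5], [3.0, 4.0]]), w,
                             marks=np.array(["cell", "fungal"]))
        p = tmp_path / "cells.csv"
        pat.to_csv(p)
        back = ls.CellPattern.from_csv(p, w)
        np.testing.assert_allclose(back.points, pat.points)
        assert list(back.marks) == ["cell", "fungal"]

    def test_feature_mask_files_round_trip(self, tmp_path):
        labels = np.zeros((6, 6), np.int32)
        labels[0, 0], labels[3, 3] = 1, 2
        w = ls.ObservationWindow(6, 6, 0.5)
        mask = ls.FeatureMask(labels, {1: "cell", 2: "fungal"}, w)
        mask.to_files(tmp_path / "m.tif", tmp_path / "c.csv")
        back = ls.FeatureMask.from_files(tmp_path / "m.tif",
                                         tmp_path / "c.csv", 0.5)
        np.testing.assert_array_equal(back.labels, labels)
        assert back.classes == mask.classes

    def test_tile_offsets_schema(self, tmp_path):
        p = tmp_path / "off.csv"
        p.write_text("tile,offset_x_px,offset_y_px\nt1.tif,0,0\nt2.tif,900,12\n")
        df = read_tile_offsets(p)
        assert df.loc[1, "offset_x_px"] == 900
        p.write_text("tile,dx\nt1,0\n")
        with pytest.raises(ValueError):
            read_tile_offsets(p)
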