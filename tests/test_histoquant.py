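"""Mosaic planning, tiling, cell classification, patch scores, filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from necrotherm.errors import (DegenerateHistogramError, DimensionError,
                               InvalidParameterError)
from necrotherm.histoquant import (CellClassRules, NecrosisMap,
                                   SectionImage, multilevel_otsu,
                                   necrosis_from_patch, patch_fractions,
                                   plan_mosaic, segment_cells, split_section,
                                   stage1_centroid, stage2_filter,
                                   stitch_section, classify_cells)


class TestMosaic:
    @pytest.mark.parametrize("w, h, tiles, tile_w, tile_h", [
        (30_720, 30_976, 1024, 960, 968),
        (76_800, 81_664, 8192, 1200, 638),
        (103_680, 101_376, 16_384, 810, 792),
    ])
    def test_printed_decompositions(self, w, h, tiles, tile_w, tile_h):
        plan = plan_mosaic(w, h)
        assert plan.n_tiles == tiles
        assert (plan.tile_w, plan.tile_h) == (tile_w, tile_h)

    @given(w=st.integers(1, 200_000), h=st.integers(1, 200_000))
    def test_plan_properties(self, w, h):
        plan = plan_mosaic(w, h)
        assert plan.tile_w * plan.tile_h * 4 <= plan.byte_bound
        # power-of-two mosaic dimensions
        assert plan.mosaic_cols & (plan.mosaic_cols - 1) == 0
        assert plan.mosaic_rows & (plan.mosaic_rows - 1) == 0

    def test_split_stitch_round_trip(self):
        rng = np.random.default_rng(0)
        raster = rng.integers(0, 255, size=(1536, 2048, 3), dtype=np.uint8)
        plan = plan_mosaic(2048, 1536, byte_bound=512 * 512 * 4)
        tiles = split_section(raster, plan)
        assert len(tiles) == plan.n_tiles
        # concatenated extents reproduce the raster exactly
        assert np.array_equal(stitch_section(tiles, plan), raster)

    def test_missing_tile_named(self):
        raster = np.zeros((64, 64, 3), dtype=np.uint8)
        plan = plan_mosaic(64, 64, byte_bound=32 * 32 * 4)
        tiles = split_section(raster, plan)
        tiles[3] = None
        with pytest.raises(DimensionError, match=r"row 1, col 1"):
            stitch_section(tiles, plan)


class TestSegmentation:
    def test_blank_tile_has_no_cells(self):
        tile = np.full((256, 256, 3), 255, dtype=np.uint8)
        seg = segment_cells(tile, um_per_px=1.0)
        assert seg.n_cells == 0

    def test_fifty_disks_recovered(self):
        # 50 non-touching disks on a grid: all found, centroids within 1 px.
        rng = np.random.default_rng(1)
        tile = np.full((500, 500, 3), 245, dtype=np.uint8)
        truth = []
        for i in range(50):
            r, c = 30 + 60 * (i // 10) + rng.integers(-5, 5), \
                30 + 48 * (i % 10) + rng.integers(-5, 5)
            yy, xx = np.mgrid[:500, :500]
            mask = (yy - r) ** 2 + (xx - c) ** 2 <= 4 ** 2
            tile[mask] = (170, 180, 190)
            truth.append((r, c))
        seg = segment_cells(tile, um_per_px=1.0)
        assert seg.n_cells == 50
        found = seg.cells[["centroid_row", "centroid_col"]].to_numpy()
        for r, c in truth:
            d = np.min(np.hypot(found[:, 0] - r, found[:, 1] - c))
            assert d <= 1.0

    def test_touching_disks_split_by_watershed(self):
        tile = np.full((100, 100, 3), 245, dtype=np.uint8)
        yy, xx = np.mgrid[:100, :100]
        for cy, cx in ((50, 42), (50, 55)):
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= 8 ** 2
            tile[mask] = (110, 100, 90)
        seg = segment_cells(tile, um_per_px=1.0)
        assert seg.n_cells == 2


class TestClassification:
    @pytest.mark.parametrize("rgb, expected", [
        ((100, 100, 100), "brown"),
        ((170, 200, 200), "blue"),
        ((255, 255, 255), "unclassified"),
    ])
    def test_examples(self, rgb, expected):
        from necrotherm.histoquant import CellSegmentation
        cells = pd.DataFrame({"label": [1], "area_um2": [50.0],
                              "r_mean": [rgb[0]], "g_mean": [rgb[1]],
                              "b_mean": [rgb[2]], "centroid_row": [5.0],
                              "centroid_col": [5.0]})
        seg = CellSegmentation(labels=np.zeros((10, 10), int), cells=cells,
                               um_per_px=1.0)
        out = classify_cells(seg)
        assert out["cell_class"].iloc[0] == expected

    @given(r=st.integers(0, 255), g=st.integers(0, 255),
           b=st.integers(0, 255))
    def test_boxes_mutually_exclusive(self, r, g, b):
        rules = CellClassRules()
        assert not (rules.is_brown(r, g, b) and rules.is_blue(r, g, b))

    def test_overlapping_boxes_rejected(self):
        with pytest.raises(InvalidParameterError):
            CellClassRules(brown_g_max=200.0)


def cell_row(cls, area, row_px, col_px):
    return {"area_um2": area, "cell_class": cls,
            "centroid_row": row_px, "centroid_col": col_px}


class TestPatchScores:
    def test_blue_only_patch(self):
        cells = pd.DataFrame([cell_row("blue", 50.0, 10.0, 10.0),
                              cell_row("blue", 60.0, 20.0, 30.0)])
        stats = patch_fractions(cells, 200, 200, um_per_px=1.0)
        assert stats.gamma[0, 0] == 1.0
        assert stats.rho_brown[0, 0] == 0.0
        assert necrosis_from_patch(stats.gamma[0, 0],
                                   stats.rho_brown[0, 0]) == 100.0

    def test_equal_blue_brown(self):
        cells = pd.DataFrame([cell_row("blue", 50.0, 10.0, 10.0),
                              cell_row("brown", 50.0, 20.0, 30.0)])
        stats = patch_fractions(cells, 200, 200, um_per_px=1.0)
        assert stats.gamma[0, 0] == 0.5

    def test_empty_patch_flagged_undefined(self):
        cells = pd.DataFrame([cell_row("unclassified", 50.0, 10.0, 10.0)])
        stats = patch_fractions(cells, 200, 200, um_per_px=1.0)
        assert not stats.defined[0, 0]
        assert np.isnan(stats.gamma[0, 0])
        assert necrosis_from_patch(stats.gamma[0, 0],
                                   stats.rho_brown[0, 0]) == 0.0

    def test_truncated_edge_patch_area(self):
        # 300x200 px at 1 um/px: 2 columns, the second 100 um wide.
        cells = pd.DataFrame([cell_row("blue", 10.0, 50.0, 250.0)])
        stats = patch_fractions(cells, 300, 200, um_per_px=1.0)
        assert stats.patch_area.shape == (1, 2)
        assert stats.patch_area[0, 1] == pytest.approx(200.0 * 100.0)

    def test_missing_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            patch_fractions(pd.DataFrame(), 100, 100, um_per_px=0.0)

    @pytest.mark.parametrize("gamma, rho, expected", [
        (1.0, 0.0, 100.0),
        (0.0, 0.37, 0.0),
        (0.5, 0.01, 50.0 * np.exp(-1.0)),
    ])
    def test_score_examples(self, gamma, rho, expected):
        assert necrosis_from_patch(gamma, rho) == pytest.approx(expected)

    def test_score_monotonicity(self):
        g = np.linspace(0, 1, 11)
        assert np.all(np.diff(necrosis_from_patch(g, 0.005)) > 0)
        r = np.linspace(0, 0.05, 11)
        assert np.all(np.diff(necrosis_from_patch(0.8, r)) < 0)


def brute_force_otsu(values, n_thresholds, nbins):
    """Exhaustive search over threshold tuples on the same histogram."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    scaled = (values - lo) / (hi - lo) * (nbins - 1.0)
    hist, edges = np.histogram(scaled, bins=nbins, range=(0, nbins - 1))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best, best_th = -np.inf, None
    total = hist.sum()
    for combo in itertools.combinations(range(1, nbins), n_thresholds):
        cuts = (0, *combo, nbins)
        var = 0.0
        ok = True
        for a, b in zip(cuts[:-1], cuts[1:]):
            w = hist[a:b].sum()
            if w == 0:
                ok = False
                break
            mu = (hist[a:b] * centers[a:b]).sum() / w
            var += w / total * mu ** 2
        if ok and var > best:
            best, best_th = var, combo
    th = np.array([centers[t - 1] + 0.5 for t in best_th])
    return th / (nbins - 1.0) * (hi - lo) + lo


class TestMultilevelOtsu:
    def test_quadrimodal_thresholds_between_modes(self):
        rng = np.random.default_rng(2)
        modes = [10, 80, 160, 230]
        values = np.concatenate([m + rng.normal(0, 2.0, 300)
                                 for m in modes])
        th = multilevel_otsu(values, 3)
        for t, (a, b) in zip(th, zip(modes[:-1], modes[1:])):
            assert a < t < b

    def test_single_threshold_matches_brute_scan(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(40, 5, 400),
                                 rng.normal(180, 8, 400)])
        th = multilevel_otsu(values, n_thresholds=1, nbins=64)
        brute = brute_force_otsu(values, 1, 64)
        assert abs(th[0] - brute[0]) <= (values.max() - values.min()) / 63

    def test_three_thresholds_match_exhaustive_search(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(m, 3.0, 200)
                                 for m in (15, 90, 150, 240)])
        th = multilevel_otsu(values, n_thresholds=3, nbins=32)
        brute = brute_force_otsu(values, 3, 32)
        step = (values.max() - values.min()) / 31
        assert np.all(np.abs(th - brute) <= step)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.random(500) * 100
        th1 = multilevel_otsu(values, 3)
        th2 = multilevel_otsu(values[::-1].copy(), 3)
        assert np.array_equal(th1, th2)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            multilevel_otsu(np.full(100, 7.0), 3)


def disk_map(shape, center, radius, value, base=None):
    vals = np.zeros(shape) if base is None else base.copy()
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    vals[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = \
        value
    return vals


def quadrimodal_lesion(shape=(41, 41), center=(20, 20)):
    """Concentric lesion emulating the quadrimodal map histogram:
    background 0, low 30, intermediate 60, high 90."""
    vals = disk_map(shape, center, 12, 30.0)
    vals = disk_map(shape, center, 9, 60.0, vals)
    return disk_map(shape, center, 6, 90.0, vals)


class TestArtifactFilter:
    def test_central_disk_centroid(self):
        vals = quadrimodal_lesion()
        maps = [NecrosisMap(values=vals), NecrosisMap(values=vals)]
        cy, cx = stage1_centroid(maps)
        assert abs(cy - 20) <= 1 and abs(cx - 20) <= 1

    def test_max_component_beats_peripheral_blob(self):
        # A weaker peripheral blob also passes the threshold, but the
        # component containing the global maximum wins.
        vals = quadrimodal_lesion()
        vals = disk_map((41, 41), (7, 33), 4, 70.0, vals)
        cy, cx = stage1_centroid([vals, vals])
        assert abs(cy - 20) <= 1 and abs(cx - 20) <= 1

    def test_all_zero_maps_rejected(self):
        maps = [np.zeros((10, 10)), np.zeros((10, 10))]
        with pytest.raises(DegenerateHistogramError):
            stage1_centroid(maps)

    def test_disk_survives_blobs_discarded(self):
        # One convex lesion disk plus two scattered artifact blobs; the
        # component nearest the stage-1 centroid survives stage 2 and the
        # scattered regions are removed.
        vals = quadrimodal_lesion()
        vals = disk_map((41, 41), (5, 5), 3, 80.0, vals)
        vals = disk_map((41, 41), (35, 30), 3, 70.0, vals)
        nmap = NecrosisMap(values=vals)
        res = stage2_filter(nmap, (20.0, 20.0))
        assert not res.warning
        kept = res.filtered.values > 0
        yy, xx = np.mgrid[:41, :41]
        inside_disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 9 ** 2
        assert kept[inside_disk].all()
        assert not (kept & ((yy - 5) ** 2 + (xx - 5) ** 2 <= 9)).any()
        assert not (kept & ((yy - 35) ** 2 + (xx - 30) ** 2 <= 9)).any()

    def test_low_solidity_cross_discarded(self):
        # A thin plus-shape (arms 2 wide, 21 long: area 80, convex hull
        # ~220, solidity ~0.36) must be dropped even when it is the only
        # candidate above threshold.
        vals = np.zeros((41, 41))
        vals[19:21, 5:26] = 90.0
        vals[5:26, 19:21] = 60.0
        vals[0:3, 30:36] = 30.0   # low-mode blob, below the second cut
        res = stage2_filter(NecrosisMap(values=vals), (15.0, 15.0))
        assert res.warning and res.kept_label is None
        assert not res.filtered.values.any()

    def test_filtered_map_bounded_by_input(self, quantified_section):
        nmap, _, _ = quantified_section
        centroid = stage1_centroid([nmap, nmap])
        res = stage2_filter(nmap, centroid)
        assert np.all(res.filtered.values <= nmap.values + 1e-12)

    def test_solidity_of_convex_disk_kept(self):
        vals = quadrimodal_lesion(shape=(31, 31), center=(15, 15))
        res = stage2_filter(NecrosisMap(values=vals), (15.0, 15.0))
        assert res.kept_label is not None and not res.warning
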