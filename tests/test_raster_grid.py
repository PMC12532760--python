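"""Raster series I/O, cropping, and landscape grid construction."""

import numpy as np
import pytest
import shapely

from landmetrics import (
    CategoricalRasterSeries,
    ClassCatalog,
    ClassDef,
    assign_continents,
    build_grid,
    crop_to_polygon,
    extract_landscape,
    load_series,
)
from landmetrics.geotiff import GridGeoref, read_categorical, write_categorical


def small_catalog():
    return ClassCatalog([
        ClassDef(0, "ocean", is_water=True, is_ocean=True, is_land=False),
        ClassDef(1, "class_1"),
        ClassDef(2, "class_2"),
    ])


def make_series(data, cell_size=1.0, nodata=255, catalog=None, years=None):
    data = np.asarray(data)
    years = years or list(range(1992, 1992 + data.shape[0]))
    return CategoricalRasterSeries(
        years=years, data=data,
        georef=GridGeoref(0.0, data.shape[1] * cell_size, cell_size),
        nodata=nodata, catalog=catalog or small_catalog(),
    )


class TestGeoTiffRoundTrip:
    def test_write_read_preserves_data_and_georef(self, tmp_path):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, (15, 12)).astype(np.uint8)
        g = GridGeoref(100.0, 250.0, 2.0)
        p = tmp_path / "x.tif"
        write_categorical(p, a, g, nodata=255)
        b, g2, nd = read_categorical(p)
        assert np.array_equal(a, b)
        assert g2 == g and nd == 255


class TestLoadSeries:
    def _write_years(self, tmp_path, shapes, years=(1992, 1993, 1994)):
        paths = []
        for year, shape in zip(years, shapes):
            a = np.ones(shape, np.uint8)
            p = tmp_path / f"lulc_{year}.tif"
            write_categorical(p, a, GridGeoref(0, shape[0] * 1.0, 1.0), 255)
            paths.append(p)
        return paths

    def test_years_sorted_ascending(self, tmp_path):
        paths = self._write_years(tmp_path, [(8, 8)] * 3)
        series = load_series(reversed(paths), small_catalog())
        assert series.years == [1992, 1993, 1994]

    def test_geometry_mismatch_names_offender(self, tmp_path):
        paths = self._write_years(tmp_path, [(8, 8), (9, 8), (8, 8)])
        with pytest.raises(ValueError, match="1993"):
            load_series(paths, small_catalog())

    def test_unknown_code_listed(self, tmp_path):
        a = np.full((5, 5), 7, np.uint8)
        p = tmp_path / "lulc_1992.tif"
        write_categorical(p, a, GridGeoref(0, 5.0, 1.0), 255)
        with pytest.raises(ValueError, match="7"):
            load_series([p], small_catalog())


class TestCrop:
    def test_identity_crop(self):
        series = make_series(np.ones((2, 10, 10), np.uint8))
        region = shapely.box(-1, -1, 11, 11)
        out = crop_to_polygon(series, region)
        assert np.array_equal(out.data, series.data)

    def test_left_half_keeps_right_half_nodata(self):
        series = make_series(np.ones((2, 10, 10), np.uint8))
        region = shapely.box(0, 0, 5, 10)  # left 5 columns
        out = crop_to_polygon(series, region)
        assert out.shape == (10, 5)
        assert (out.data == 1).all()
        # window is clipped, so right-half cells are simply gone;
        # a region overlapping partially leaves NoData inside the window
        notch = shapely.box(0, 0, 5, 10).union(shapely.box(5, 0, 10, 4))
        out2 = crop_to_polygon(series, notch)
        assert out2.shape == (10, 10)
        assert (out2.data[:, :6, 5:] == 255).all()

    def test_inner_square_clips_window(self):
        series = make_series(np.ones((1, 10, 10), np.uint8))
        region = shapely.box(2, 2, 5, 5)  # covers cell centers (2.5..4.5)
        out = crop_to_polygon(series, region)
        assert out.shape == (3, 3)
        assert out.georef.x0 == 2.0

    def test_crop_idempotent(self):
        series = make_series(np.ones((2, 10, 10), np.uint8))
        region = shapely.box(1, 1, 7, 8)
        once = crop_to_polygon(series, region)
        twice = crop_to_polygon(once, region)
        assert np.array_equal(once.data, twice.data)
        assert once.georef == twice.georef

    def test_empty_intersection_raises(self):
        series = make_series(np.ones((1, 5, 5), np.uint8))
        with pytest.raises(ValueError, match="intersect"):
            crop_to_polygon(series, shapely.box(100, 100, 101, 101))


class TestBuildGrid:
    def test_partial_windows_dropped(self):
        series = make_series(np.ones((1, 25, 25), np.uint8))
        grid = build_grid(series, 10.0)
        assert len(grid) == 4
        assert grid.cells_per_side == 10
        assert sorted(grid.landscape_ids) == [0, 1, 2, 3]

    def test_all_ocean_window_removed(self):
        data = np.ones((2, 20, 20), np.uint8)
        data[:, :10, :10] = 0  # ocean in both years
        series = make_series(data)
        grid = build_grid(series, 10.0)
        assert len(grid) == 3
        assert 0 not in grid.landscape_ids

    def test_window_with_land_in_any_year_retained(self):
        data = np.ones((2, 20, 20), np.uint8)
        data[0, :10, :10] = 0  # ocean in 1992 only
        series = make_series(data)
        assert len(build_grid(series, 10.0)) == 4

    def test_nodata_only_window_removed(self):
        data = np.ones((1, 20, 20), np.uint8)
        data[:, 10:, 10:] = 255
        series = make_series(data)
        grid = build_grid(series, 10.0)
        assert 3 not in grid.landscape_ids

    def test_non_multiple_extent_rejected(self):
        series = make_series(np.ones((1, 20, 20), np.uint8), cell_size=2.0)
        with pytest.raises(ValueError, match="multiple"):
            build_grid(series, 7.0)

    def test_all_removed_raises(self):
        series = make_series(np.zeros((1, 20, 20), np.uint8))
        with pytest.raises(ValueError, match="survive"):
            build_grid(series, 10.0)

    def test_tessellation_partition(self):
        """Kept windows + removed/dropped remainder tile the raster once."""
        data = np.ones((1, 25, 25), np.uint8)
        data[:, :10, :10] = 0
        series = make_series(data)
        grid = build_grid(series, 10.0)
        covered = np.zeros((25, 25), int)
        for lid in grid.landscape_ids:
            r0, c0 = grid.window(lid)
            covered[r0 : r0 + 10, c0 : c0 + 10] += 1
        assert covered.max() == 1
        assert covered.sum() == len(grid) * 100

    def test_grid_determinism(self):
        series = make_series(np.ones((1, 30, 30), np.uint8))
        g1, g2 = build_grid(series, 10.0), build_grid(series, 10.0)
        assert g1.entries.equals(g2.entries)


class TestExtractAndContinents:
    def test_window_geometry(self):
        series = make_series(np.ones((1, 20, 20), np.uint8))
        grid = build_grid(series, 10.0)
        w = extract_landscape(series, grid, 0, 1992)
        assert w.shape == (10, 10)
        assert (w == 1).all()

    def test_adjacent_windows_disjoint(self):
        data = np.ones((1, 20, 20), np.uint8)
        data[0, :, 10:] = 2
        series = make_series(data)
        grid = build_grid(series, 10.0)
        w0 = extract_landscape(series, grid, 0, 1992)
        w1 = extract_landscape(series, grid, 1, 1992)
        assert (w0 == 1).all() and (w1 == 2).all()

    def test_unknown_id_or_year(self):
        series = make_series(np.ones((1, 20, 20), np.uint8))
        grid = build_grid(series, 10.0)
        with pytest.raises(KeyError):
            extract_landscape(series, grid, 99, 1992)
        with pytest.raises(KeyError):
            extract_landscape(series, grid, 0, 1890)

    def test_continent_assignment_and_tie_break(self):
        series = make_series(np.ones((1, 20, 20), np.uint8))
        grid = build_grid(series, 10.0)
        # centroids at x,y in {5,15}; boundary between west and east at x=5
        west = ("west", shapely.box(0, 0, 5, 20))
        east = ("east", shapely.box(5, 0, 20, 20))
        labeled = assign_continents(grid, [west, east])
        by_pos = labeled.entries.set_index(["lrow", "lcol"])["continent"]
        assert by_pos[(0, 0)] == "west"  # centroid x=5 on shared edge: first wins
        assert by_pos[(0, 1)] == "east"

    def test_unassigned_label(self):
        series = make_series(np.ones((1, 20, 20), np.uint8))
        grid = build_grid(series, 10.0)
        labeled = assign_continents(grid, [("tiny", shapely.box(0, 0, 1, 1))])
        assert (labeled.entries["continent"] == "unassigned").sum() == 4
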