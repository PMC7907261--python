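import numpy as np
import pandas as pd
import pytest

from ito3de.grid import (
    CategoricalGrid,
    GeometryError,
    Grid,
    ZoneMap,
    area_proportions,
    euclidean_distance,
    focal_statistic,
    zonal_mean,
    zonal_paint,
    zonal_spread,
)

from .oracles import distance_bf, focal_bf


class TestGrid:
    def test_shape_and_geometry(self):
        g = Grid(np.zeros((3, 5)), cell_size=30.0, origin=(100.0, 200.0))
        assert (g.nrows, g.ncols) == (3, 5)
        assert g.cell_area_ha == pytest.approx(0.09)
        xs, ys = g.cell_centers()
        assert xs[0, 0] == pytest.approx(115.0)  # origin_x + 0.5*cell
        assert ys[0, 0] == pytest.approx(185.0)  # origin_y - 0.5*cell

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            Grid(np.zeros(4))
        with pytest.raises(ValueError):
            Grid(np.zeros((2, 2)), cell_size=0.0)

    def test_geometry_mismatch_is_an_error(self, small_grid):
        other = Grid(np.zeros((10, 10)), cell_size=25.0)
        with pytest.raises(GeometryError):
            small_grid.require_same_geometry(other)

    def test_nodata_roundtrip_through_nan(self, small_grid):
        small_grid.values[0, 0] = small_grid.nodata
        back = small_grid.from_nan(small_grid.to_nan())
        assert np.array_equal(back.values, small_grid.values)

    def test_categorical_requires_legend_coverage(self):
        with pytest.raises(ValueError, match="class_table"):
            CategoricalGrid(np.array([[1, 7]]), class_table={1: "a"})


class TestFocalStatistic:
    def test_constant_grid_range_is_zero(self):
        g = Grid(np.full((6, 6), 3.7))
        out = focal_statistic(g, 5, "range")
        assert np.allclose(out.values, 0.0)

    def test_center_max_propagates_through_window(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 9.0
        out = focal_statistic(Grid(vals), 3, "max")
        assert np.allclose(out.values, 9.0)

    @pytest.mark.parametrize("stat", ["range", "mean", "min", "max"])
    def test_matches_bruteforce_with_nodata(self, stat, rng):
        vals = rng.uniform(0, 50, (10, 10))
        vals[rng.random((10, 10)) < 0.2] = -9999.0
        g = Grid(vals)
        out = focal_statistic(g, 7, stat)
        expect = focal_bf(vals, 7, stat, -9999.0)
        assert np.allclose(out.values, expect)

    def test_all_nodata_window_stays_nodata(self):
        vals = np.full((5, 5), -9999.0)
        vals[0, 0] = 1.0
        out = focal_statistic(Grid(vals), 3, "mean")
        assert out.values[4, 4] == -9999.0
        assert out.values[0, 0] == 1.0

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_invalid_window_rejected(self, small_grid, window):
        with pytest.raises(ValueError):
            focal_statistic(small_grid, window)


class TestEuclideanDistance:
    def test_single_source_neighbors(self):
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        d = euclidean_distance(Grid(mask, cell_size=30.0))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(30.0)
        assert d.values[1, 1] == pytest.approx(30.0 * np.sqrt(2))

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="source"):
            euclidean_distance(Grid(np.zeros((4, 4))))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((20, 20)) < 0.05).astype(float)
        mask[0, 0] = 1  # guarantee a source
        g = Grid(mask, cell_size=30.0)
        out = euclidean_distance(g)
        expect = distance_bf(mask, 30.0)
        assert np.max(np.abs(out.values - expect)) < 1e-6 * 30.0


class TestZonalOps:
    def test_spread_intensity_arithmetic(self, two_zone_map):
        # 100 kg over 4 cells of 0.09 ha -> 277.78 kg/ha
        mask = Grid(np.array([[1.0, 1, 0, 0], [1, 1, 0, 0]]), cell_size=30.0)
        out = zonal_spread(two_zone_map, {1: 100.0, 2: 0.0}, mask)
        assert out.values[0, 0] == pytest.approx(100.0 / (4 * 0.09))
        assert np.all(out.values[:, 2:] == 0.0)

    def test_spread_zero_total_gives_zeros(self, two_zone_map):
        mask = Grid(np.ones((2, 4)), cell_size=30.0)
        out = zonal_spread(two_zone_map, {1: 0.0, 2: 0.0}, mask)
        assert np.all(out.values == 0.0)

    def test_spread_conserves_mass_per_zone(self, two_zone_map, rng):
        mask = Grid((rng.random((2, 4)) < 0.8).astype(float), cell_size=30.0)
        mask.values[0, 0] = 1.0
        mask.values[0, 2] = 1.0
        totals = {1: 57.3, 2: 11.1}
        out = zonal_spread(two_zone_map, totals, mask)
        for z, total in totals.items():
            zsel = two_zone_map.zone_mask(z) & (mask.values == 1)
            recovered = out.values[zsel].sum() * out.cell_area_ha
            assert recovered == pytest.approx(total, rel=1e-9)

    def test_spread_warns_and_drops_maskless_zone(self, two_zone_map):
        mask = Grid(np.array([[1.0, 1, 0, 0], [1, 1, 0, 0]]), cell_size=30.0)
        with pytest.warns(UserWarning, match="no mask cells"):
            out = zonal_spread(two_zone_map, {1: 1.0, 2: 99.0}, mask)
        assert np.all(out.values[:, 2:] == 0.0)

    def test_paint_assigns_intensive_values(self, two_zone_map):
        out = zonal_paint(two_zone_map, {1: 3.0, 2: 7.0})
        assert np.all(out.values[:, :2] == 3.0)
        assert np.all(out.values[:, 2:] == 7.0)

    def test_zonal_mean_constant_and_checkerboard(self, two_zone_map):
        const = Grid(np.full((2, 4), 5.0), cell_size=30.0)
        assert np.allclose(zonal_mean(two_zone_map, const), 5.0)
        cb = Grid(np.array([[0.0, 2, 0, 2], [2, 0, 2, 0]]), cell_size=30.0)
        assert np.allclose(zonal_mean(two_zone_map, cb), 1.0)

    def test_zonal_mean_matches_bruteforce(self, two_zone_map, rng):
        g = Grid(rng.uniform(0, 9, (2, 4)), cell_size=30.0)
        means = zonal_mean(two_zone_map, g)
        for z in (1, 2):
            assert means[z] == pytest.approx(g.values[two_zone_map.zone_mask(z)].mean())

    def test_zone_table_grid_bijection_enforced(self, two_zone_map):
        bad = two_zone_map.table.drop(index=2)
        with pytest.raises(ValueError, match="zone ids"):
            ZoneMap(zone_grid=two_zone_map.zone_grid, table=bad)


class TestAreaProportions:
    def test_half_half(self):
        g = CategoricalGrid(
            np.array([[1, 1], [2, 2]]), class_table={1: "a", 2: "b"}
        )
        p = area_proportions(g)
        assert p["a"] == pytest.approx(50.0)
        assert p.sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_class_and_all_nodata(self):
        g = CategoricalGrid(np.ones((3, 3), dtype=int), class_table={1: "only"})
        assert area_proportions(g)["only"] == pytest.approx(100.0)
        empty = CategoricalGrid(np.full((2, 2), -1), class_table={})
        with pytest.raises(ValueError):
            area_proportions(empty)

    def test_random_labels_match_hand_count(self, rng):
        vals = rng.integers(1, 4, (15, 15))
        g = CategoricalGrid(vals, class_table={1: "a", 2: "b", 3: "c"})
        p = area_proportions(g)
        for code, label in g.class_table.items():
            assert p[label] == pytest.approx((vals == code).mean() * 100)
        assert p.sum() == pytest.approx(100.0, abs=1e-6)
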