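import numpy as np
import pytest

from ito3de.grid import Grid
from ito3de.hotspots import (
    Z_THRESHOLDS,
    build_grid_weights,
    build_zone_weights,
    classify_hotspots,
    gi_bin,
    gi_star,
    hotspot_analysis,
)

from .oracles import gi_star_bf, queen_weights_bf


def geometry(nr=3, nc=3):
    return Grid(np.zeros((nr, nc)), cell_size=30.0)


class TestWeights:
    def test_rook_center_has_five_neighbors_with_self(self):
        W = build_grid_weights(geometry(), "rook", include_self=True)
        center = W.matrix[4].toarray().ravel()
        assert center.sum() == 5
        assert center[4] == 1

    def test_queen_center_has_nine(self):
        W = build_grid_weights(geometry(), "queen", include_self=True)
        assert W.matrix[4].toarray().sum() == 9

    def test_self_exclusion(self):
        W = build_grid_weights(geometry(), "queen", include_self=False)
        assert W.matrix[4].toarray().ravel()[4] == 0
        assert W.matrix[4].toarray().sum() == 8

    def test_distance_band_equals_queen_on_grid(self):
        geom = geometry(6, 6)
        q = build_grid_weights(geom, "queen")
        d = build_grid_weights(
            geom, "fixed_distance_band", distance_band=1.5 * geom.cell_size
        )
        assert (q.matrix != d.matrix).nnz == 0

    def test_symmetry(self):
        W = build_grid_weights(geometry(5, 4), "queen").matrix
        assert (W != W.T).nnz == 0

    def test_zone_adjacency_from_shared_edges(self, two_zone_map):
        W = build_zone_weights(two_zone_map, "rook")
        assert np.array_equal(W.matrix.toarray(), np.ones((2, 2)))

    def test_isolated_zone_warns(self):
        import pandas as pd

        from ito3de.grid import CategoricalGrid, ZoneMap

        vals = np.full((3, 5), 1)
        vals[:, 4] = 2
        vals[:, 3] = -1  # nodata corridor isolates zone 2
        zg = CategoricalGrid(vals, class_table={1: "a", 2: "b"}, nodata=-1)
        zm = ZoneMap(
            zone_grid=zg,
            table=pd.DataFrame({"name": ["a", "b"]}, index=pd.Index([1, 2], name="zone")),
        )
        with pytest.warns(UserWarning, match="no neighbors"):
            build_zone_weights(zm, "queen")


class TestGiStar:
    def test_constant_field_is_degenerate(self):
        W = build_grid_weights(geometry(), "queen")
        with pytest.raises(ValueError, match="constant"):
            gi_star(np.ones(9), W)

    def test_negating_field_negates_z(self, rng):
        W = build_grid_weights(geometry(5, 5), "queen")
        x = rng.uniform(0, 10, 25)
        z_pos, _ = gi_star(x, W)
        z_neg, _ = gi_star(-x, W)
        assert np.allclose(z_pos, -z_neg, atol=1e-12)

    def test_location_scale_invariance(self, rng):
        W = build_grid_weights(geometry(6, 6), "queen")
        x = rng.uniform(0, 10, 36)
        z, _ = gi_star(x, W)
        z2, _ = gi_star(3.7 * x + 11.0, W)
        assert np.max(np.abs(z - z2)) < 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        nr = nc = 8
        x = rng.uniform(0, 100, nr * nc)
        W = build_grid_weights(geometry(nr, nc), "queen")
        z, p = gi_star(x, W)
        z_bf = gi_star_bf(x, queen_weights_bf(nr, nc))
        assert np.max(np.abs(z - z_bf)) < 1e-10
        assert np.all((p > 0) & (p <= 1))

    def test_planted_block_is_hot_and_antipode_is_not(self, rng):
        """A high-mean block in a noise field lights up +3 inside only."""
        nr = nc = 15
        vals = rng.normal(0, 1, (nr, nc))
        vals[2:6, 2:6] += 8.0
        W = build_grid_weights(geometry(nr, nc), "queen")
        z, _ = gi_star(vals.ravel(), W)
        bins = gi_bin(z).reshape(nr, nc)
        assert np.all(bins[3:5, 3:5] == 3)
        assert np.all(bins[10:, 10:] <= 0)


class TestGiBin:
    @pytest.mark.parametrize(
        "z,expected",
        [(3.1, 3), (2.7, 3), (2.0, 2), (1.7, 1), (0.0, 0), (-2.0, -2), (-3.0, -3)],
    )
    def test_threshold_table(self, z, expected):
        assert gi_bin(np.array([z]))[0] == expected

    def test_thresholds_are_two_sided_normal_quantiles(self):
        from scipy import stats

        for thr, alpha in zip(Z_THRESHOLDS, (0.10, 0.05, 0.01)):
            assert 2 * stats.norm.sf(thr) == pytest.approx(alpha, rel=1e-9)

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValueError):
            gi_bin(np.array([np.nan]))

    def test_fdr_is_no_more_liberal(self, rng):
        z = rng.normal(0, 1.5, 200)
        plain = np.abs(gi_bin(z))
        corrected = np.abs(gi_bin(z, correction="fdr"))
        assert np.all(corrected <= plain)

    def test_labels(self):
        assert classify_hotspots(np.array([3]))[0] == "Hot Spot 99% Confidence"
        assert classify_hotspots(np.array([0]))[0] == "Not Significant"
        assert classify_hotspots(np.array([-1]))[0] == "Cold Spot 90% Confidence"


class TestHotspotAnalysis:
    def test_zone_level_table_shape(self, demo_scene, demo_surface):
        surface, table = hotspot_analysis(demo_surface.A, zones=demo_scene.inputs.zones)
        assert len(table) == len(demo_scene.inputs.zones.zone_ids)
        assert set(table.columns) == {"unit", "x", "z", "p", "gi_bin", "class"}
        assert np.all(np.sign(table["gi_bin"]) == np.sign(table["z"]) * (table["gi_bin"] != 0))

    def test_cell_level_covers_planted_cluster(self, demo_scene, demo_surface):
        surface, _ = hotspot_analysis(demo_surface.A, zones=None)
        bins = surface.gi_bin.reshape(demo_surface.A.shape)
        rows, cols = np.indices(demo_surface.A.shape)
        sel = (rows - 60) ** 2 + (cols - 60) ** 2 <= 10**2
        assert np.all(bins[sel] == 3)
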