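import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ito3de.grid import Grid
from ito3de.indicators import (
    CAP_VALUE,
    DEFAULT_SPECS,
    nemerow_index,
    nemerow_scalar,
    normalize_negative,
    normalize_positive,
)
from ito3de.recipes import build_indicator
from ito3de import landuse


def g(vals):
    return Grid(np.asarray(vals, dtype=float), cell_size=30.0)


class TestNormalization:
    def test_identity_at_reference_both_directions(self):
        c = g([[250.0]])
        assert normalize_positive(c, 250.0).values[0, 0] == pytest.approx(1.0)
        assert normalize_negative(c, 250.0).values[0, 0] == pytest.approx(1.0)

    def test_fertilizer_over_reference(self):
        # regional application level of 411 kg/ha against the 250 kg/ha
        # reference reads as medium risk
        out = normalize_positive(g([[411.0]]), 250.0)
        assert out.values[0, 0] == pytest.approx(1.644)

    def test_zero_raw_value(self):
        assert normalize_positive(g([[0.0]]), 5.0).values[0, 0] == 0.0
        # negative direction: zero raw value clamps to the cap
        assert normalize_negative(g([[0.0]]), 1500.0).values[0, 0] == CAP_VALUE

    def test_negative_double_reference_halves(self):
        assert normalize_negative(g([[3000.0]]), 1500.0).values[0, 0] == pytest.approx(0.5)

    def test_invalid_reference_rejected(self):
        for E in (0.0, -2.0):
            with pytest.raises(ValueError):
                normalize_positive(g([[1.0]]), E)
            with pytest.raises(ValueError):
                normalize_negative(g([[1.0]]), E)

    def test_nodata_propagates(self):
        grid = g([[1.0, -9999.0]])
        out = normalize_positive(grid, 2.0)
        assert out.values[0, 1] == -9999.0

    @settings(max_examples=120, derandomize=True)
    @given(
        c=st.floats(0.5, 1000.0),
        e=st.floats(0.5, 1000.0),
    )
    def test_positive_times_negative_is_one_off_clamp(self, c, e):
        pos = normalize_positive(g([[c]]), e).values[0, 0]
        neg = normalize_negative(g([[c]]), e).values[0, 0]
        if pos < CAP_VALUE and neg < CAP_VALUE:
            assert pos * neg == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(c=st.floats(0.0, 1e5), e=st.floats(1e-3, 1e4))
    def test_indices_stay_in_bounds(self, c, e):
        for f in (normalize_positive, normalize_negative):
            v = f(g([[c]]), e).values[0, 0]
            assert 0.0 <= v <= CAP_VALUE


class TestNemerow:
    def test_equal_subindices_are_fixed_point(self):
        grids = [g([[2.3]]) for _ in range(3)]
        assert nemerow_index(grids).values[0, 0] == pytest.approx(2.3)

    def test_hand_arithmetic(self):
        out = nemerow_index([g([[0.0]]), g([[0.0]]), g([[3.0]])])
        assert out.values[0, 0] == pytest.approx(np.sqrt(5.0))

    def test_single_subindex_is_identity(self, rng):
        grid = g(rng.uniform(0, 4, (5, 5)))
        assert np.allclose(nemerow_index([grid]).values, grid.values)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            nemerow_index([])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=6))
    def test_bounded_by_mean_and_max(self, subs):
        p = nemerow_scalar(subs)
        arr = np.asarray(subs)
        assert arr.mean() - 1e-12 <= p <= arr.max() + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=6))
    def test_homogeneous_of_degree_one(self, subs):
        assert nemerow_scalar([2 * v for v in subs]) == pytest.approx(
            2 * nemerow_scalar(subs), abs=1e-9
        )


class TestIndicatorRecipes:
    def test_directions_match_published_table(self):
        negatives = {i for i, s in DEFAULT_SPECS.items() if s.direction == "negative"}
        assert negatives == {"I8", "I10", "I11", "I12"}

    def test_slope_indicator_zero_off_farmland(self, demo_scene):
        layer = build_indicator("I7", demo_scene.inputs)
        forest = demo_scene.inputs.land_use.values == landuse.FOREST
        assert np.all(layer.grid.values[forest] == 0.0)

    def test_distance_indicator_is_reference_over_distance(self, demo_scene):
        from ito3de.grid import euclidean_distance

        layer = build_indicator("I8", demo_scene.inputs)
        dist = euclidean_distance(landuse.water_mask(demo_scene.inputs.land_use))
        far = dist.values >= 1500.0 / CAP_VALUE
        assert np.allclose(layer.grid.values[far], 1500.0 / dist.values[far])
        on_water = demo_scene.inputs.land_use.values == landuse.WATER
        assert np.all(layer.grid.values[on_water] == CAP_VALUE)

    def test_paddy_retention_reference_share_is_unity(self):
        # a zone whose paddy share equals the long-term reference scores 1.0
        spec = DEFAULT_SPECS["I12"]
        assert spec.reference / 0.3339 == pytest.approx(1.0)

    def test_all_layers_bounded(self, demo_scene):
        from ito3de.recipes import build_all_indicators

        for ind_id, layer in build_all_indicators(demo_scene.inputs).items():
            vals = layer.grid.to_nan()
            finite = vals[~np.isnan(vals)]
            assert finite.min() >= 0.0, ind_id
            assert finite.max() <= CAP_VALUE + 1e-12, ind_id

    def test_missing_zone_column_names_the_indicator(self, demo_scene):
        import dataclasses

        from ito3de.grid import ZoneMap

        inputs = demo_scene.inputs
        stripped = inputs.zones.table.drop(columns=["runoff_modulus"])
        zones = ZoneMap(zone_grid=inputs.zones.zone_grid, table=stripped)
        broken = dataclasses.replace(inputs, zones=zones)
        with pytest.raises(ValueError, match="I10"):
            build_indicator("I10", broken)

    def test_unknown_indicator_id_rejected(self, demo_scene):
        with pytest.raises(ValueError, match="I99"):
            build_indicator("I99", demo_scene.inputs, DEFAULT_SPECS["I1"])
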