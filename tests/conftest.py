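from __future__ import annotations

import numpy as np
import pytest

from ito3de import build_all_indicators, score_indicators
from ito3de.grid import CategoricalGrid, Grid, ZoneMap
from ito3de.synth import ClusterSpec, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid(rng):
    return Grid(rng.uniform(0, 100, (10, 10)), cell_size=30.0)


@pytest.fixture
def two_zone_map():
    """2x4 raster split into two zones with a small attribute table."""
    import pandas as pd

    zone_vals = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
    zg = CategoricalGrid(zone_vals, class_table={1: "west", 2: "east"}, cell_size=30.0)
    table = pd.DataFrame({"name": ["west", "east"]}, index=pd.Index([1, 2], name="zone"))
    return ZoneMap(zone_grid=zg, table=table)


@pytest.fixture(scope="session")
def demo_scene():
    """Mid-size scene with one planted high-risk cluster (shared, read-only)."""
    cfg = SceneConfig(
        nrows=120, ncols=120, n_zones=8, seed=42, clusters=(ClusterSpec((60, 60), 10, 4),)
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def demo_surface(demo_scene):
    layers = build_all_indicators(demo_scene.inputs)
    surface, dims = score_indicators(layers, epoch="epoch_1")
    return surface
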