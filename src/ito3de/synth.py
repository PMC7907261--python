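"""Seeded generator of synthetic study regions with known ground truth.

A scene emulates the input inventory of a mountainous agricultural region:
a smooth DEM with derived slope, a categorical land-use raster (paddy, dry
land, forest, water, artificial, other) with controllable class
proportions, a rainfall-erosivity layer, a Voronoi partition into
administrative zones, and a per-zone statistics table (fertilizer and
pesticide totals, livestock ratios, water-quality indices, runoff modulus,
river/lake densities). All random fields are smoothed white noise, so
spatial autocorrelation is controlled by a single length scale per layer.

Optional planted clusters perturb the *raw inputs* (fertilizer, pesticide
and erosivity) inside a disk so that the composite risk score there lands
in a chosen grade's interval — the whole scoring pipeline, not just a
classifier, is exercised when recovering them. The generator knows the
weight algebra: a per-cell increment spread over the three levers moves the
composite by exactly the requested amount, and a target that would push any
index past its cap (or below zero) raises as infeasible.

Epoch series repeat the scene with per-zone drift of the agro-intensity
statistics (and optional farmland loss), giving grade trajectories with
known expected direction for transition-matrix tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landuse
from .grid import CategoricalGrid, Grid, ZoneMap
from .indicators import CAP_VALUE, DEFAULT_SPECS
from .recipes import EpochInputs, build_all_indicators
from .scoring import GradeScale, WeightConfig, score_indicators

__all__ = [
    "ZoneStat",
    "ClusterSpec",
    "DriftSpec",
    "SceneConfig",
    "SceneTruth",
    "SyntheticScene",
    "generate_scene",
    "generate_epoch_series",
]


@dataclass(frozen=True)
class ZoneStat:
    """Normal distribution (mean, sd) a per-zone statistic is drawn from."""

    mean: float
    sd: float
    minimum: float = 0.0


@dataclass(frozen=True)
class ClusterSpec:
    """A planted high-risk disk: center cell, radius and target grade."""

    center: tuple[int, int]  # (row, col)
    radius: float  # cells
    target_grade: int  # 1..5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cluster radius must be positive")
        if not 1 <= self.target_grade <= 5:
            raise ValueError("target grade must be in 1..5")


@dataclass(frozen=True)
class DriftSpec:
    """Per-epoch-step drift applied when generating an epoch series.

    ``fertilizer_growth`` / ``pesticide_growth`` map zone id to the
    multiplicative intensity growth per epoch step (1.0 = static).
    ``farmland_loss`` converts that fraction of farmland cells to
    artificial land per step (the urbanization signal).
    """

    fertilizer_growth: dict[int, float] = field(default_factory=dict)
    pesticide_growth: dict[int, float] = field(default_factory=dict)
    farmland_loss: float = 0.0


#: Mid-interval composite values targeted for each planted grade.
_GRADE_TARGET_A = {1: 0.35, 2: 0.85, 3: 2.0, 4: 4.0, 5: 6.0}


@dataclass
class SceneConfig:
    """Everything the generator needs; the seed fixes all randomness."""

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 30.0
    n_zones: int = 12
    seed: int = 0
    #: target land-use shares (must sum to 1); farmland ~39%, water ~2%
    land_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "water": 0.02,
            "paddy": 0.17,
            "dry_land": 0.22,
            "other": 0.06,
            "artificial": 0.03,
            "forest": 0.50,
        }
    )
    landuse_smoothness: float = 10.0  # cells
    dem_smoothness: float = 25.0
    dem_base: float = 200.0  # m
    dem_amplitude: float = 500.0
    erosivity_smoothness: float = 12.0
    erosivity: ZoneStat = ZoneStat(60.0, 35.0)
    #: per-zone statistic distributions (intensities, ratios, densities)
    zone_stats: dict[str, ZoneStat] = field(
        default_factory=lambda: {
            "fertilizer_intensity": ZoneStat(330.0, 60.0),  # kg/ha of farmland
            "pesticide_intensity": ZoneStat(2.2, 0.5),
            "livestock_load_ratio": ZoneStat(0.4, 0.15),
            "livestock_facility_deficiency": ZoneStat(0.4, 0.15),
            "livestock_scale_ratio": ZoneStat(0.4, 0.15),
            "cod_index": ZoneStat(0.8, 0.25, 0.01),
            "nh3n_index": ZoneStat(0.8, 0.25, 0.01),
            "tp_index": ZoneStat(0.8, 0.25, 0.01),
            "runoff_modulus": ZoneStat(75.0, 12.0, 5.0),
            "river_density": ZoneStat(0.40, 0.08, 0.01),
            "lake_density": ZoneStat(0.025, 0.006, 0.001),
        }
    )
    clusters: tuple[ClusterSpec, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.land_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"land proportions must sum to 1, got {total}")


@dataclass
class SceneTruth:
    """Ground truth descriptor: planted clusters and true zone parameters."""

    clusters: pd.DataFrame  # center_x/y, radius_m, target_grade, target_A
    zone_params: pd.DataFrame
    config: SceneConfig


@dataclass
class SyntheticScene:
    """A complete generated epoch plus its ground truth."""

    inputs: EpochInputs
    truth: SceneTruth


# ---------------------------------------------------------------------------
# field helpers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized (zero-mean, unit-sd) smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _slope_degrees(dem: Grid) -> Grid:
    dy, dx = np.gradient(dem.values, dem.cell_size)
    return dem.like(np.degrees(np.arctan(np.hypot(dx, dy))))


def _classify_by_quantiles(
    field_vals: np.ndarray, proportions: dict[str, float]
) -> np.ndarray:
    """Threshold a continuous field into classes matching target shares.

    Class order (low field value -> high): water, paddy, dry_land, other,
    artificial, forest — keeps paddies adjacent to water and forest on the
    'opposite' end, a crude but serviceable landscape gradient.
    """
    order = ["water", "paddy", "dry_land", "other", "artificial", "forest"]
    code_of = {v: k for k, v in landuse.LAND_CLASSES.items()}
    cum = np.cumsum([proportions[name] for name in order])[:-1]
    cuts = np.quantile(field_vals, cum)
    out = np.full(field_vals.shape, code_of[order[-1]], dtype=np.int64)
    prev = -np.inf
    for name, cut in zip(order[:-1], cuts):
        out[(field_vals > prev) & (field_vals <= cut)] = code_of[name]
        prev = cut
    return out


def _voronoi_zones(
    rng: np.random.Generator, shape: tuple[int, int], n_zones: int
) -> np.ndarray:
    rr = rng.uniform(0, shape[0], n_zones)
    cc = rng.uniform(0, shape[1], n_zones)
    rows, cols = np.indices(shape)
    d2 = (rows[..., None] - rr) ** 2 + (cols[..., None] - cc) ** 2
    return np.argmin(d2, axis=-1) + 1  # zone ids 1..n


def _draw_zone_table(
    rng: np.random.Generator,
    config: SceneConfig,
    zones: np.ndarray,
    farmland: np.ndarray,
    cell_area_ha: float,
) -> pd.DataFrame:
    ids = list(range(1, config.n_zones + 1))
    cols: dict[str, np.ndarray] = {}
    for name, stat in config.zone_stats.items():
        cols[name] = np.maximum(
            rng.normal(stat.mean, stat.sd, size=len(ids)), stat.minimum
        )
    table = pd.DataFrame(cols, index=pd.Index(ids, name="zone"))
    farm_ha = np.array(
        [float((farmland & (zones == z)).sum()) * cell_area_ha for z in ids]
    )
    table["farmland_ha"] = farm_ha
    table["fertilizer_kg"] = table["fertilizer_intensity"] * farm_ha
    table["pesticide_kg"] = table["pesticide_intensity"] * farm_ha
    return table


# ---------------------------------------------------------------------------
# cluster calibration
# ---------------------------------------------------------------------------

#: levers the calibration spreads a composite increment over, with their
#: flat (dimension x indicator) weights and references
def _lever_weights(weights: WeightConfig) -> dict[str, float]:
    return {i: weights.flat_weight(i) for i in ("I1", "I2", "I4")}


def _calibrate_clusters(
    inputs: EpochInputs,
    clusters: tuple[ClusterSpec, ...],
    weights: WeightConfig,
    scale: GradeScale,
) -> tuple[EpochInputs, pd.DataFrame]:
    """Set the extras rasters so each cluster's composite hits its target."""
    geom = inputs.dem
    rows_t = []
    if not clusters:
        return inputs, pd.DataFrame(
            rows_t, columns=["center_x", "center_y", "radius_m", "target_grade", "target_A"]
        )

    layers = build_all_indicators(inputs)
    surface, _ = score_indicators(layers, weights, scale)
    A0 = surface.A.to_nan()
    lever_w = _lever_weights(weights)
    w_total = sum(lever_w.values())
    refs = {i: DEFAULT_SPECS[i].reference for i in lever_w}
    base_index = {i: layers[i].grid.to_nan() for i in lever_w}

    fert = np.zeros(geom.shape)
    pest = np.zeros(geom.shape)
    eros = np.zeros(geom.shape)
    rows, cols = np.indices(geom.shape)
    for cl in clusters:
        target_A = _GRADE_TARGET_A[cl.target_grade]
        sel = (rows - cl.center[0]) ** 2 + (cols - cl.center[1]) ** 2 <= cl.radius**2
        sel &= ~np.isnan(A0)
        if not sel.any():
            raise ValueError(f"cluster at {cl.center} covers no valid cells")
        delta_idx = (target_A - A0[sel]) / w_total  # per-index increment
        for i, raster in (("I1", fert), ("I2", pest), ("I4", eros)):
            new_index = base_index[i][sel] + delta_idx
            if (new_index > CAP_VALUE).any() or (new_index < 0).any():
                raise ValueError(
                    f"infeasible cluster target grade {cl.target_grade} at "
                    f"{cl.center}: index {i} would leave [0, {CAP_VALUE}]"
                )
            raster[sel] += delta_idx * refs[i]
        cx = geom.origin[0] + (cl.center[1] + 0.5) * geom.cell_size
        cy = geom.origin[1] - (cl.center[0] + 0.5) * geom.cell_size
        rows_t.append(
            {
                "center_x": cx,
                "center_y": cy,
                "radius_m": cl.radius * geom.cell_size,
                "target_grade": cl.target_grade,
                "target_A": target_A,
            }
        )
    out = replace(
        inputs,
        fertilizer_extra=geom.like(fert),
        pesticide_extra=geom.like(pest),
        erosivity_extra=geom.like(eros),
    )
    return out, pd.DataFrame(rows_t)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one complete epoch; identical seeds give identical scenes."""
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    cs = config.cell_size

    dem_vals = config.dem_base + config.dem_amplitude * (
        _smooth_field(rng, shape, config.dem_smoothness) * 0.5 + 0.5
    )
    dem = Grid(dem_vals, cell_size=cs)
    slope = _slope_degrees(dem)

    lu_field = _smooth_field(rng, shape, config.landuse_smoothness)
    lu_vals = _classify_by_quantiles(lu_field, config.land_proportions)
    land_use = CategoricalGrid(
        lu_vals, class_table=dict(landuse.LAND_CLASSES), cell_size=cs
    )

    ero_field = _smooth_field(rng, shape, config.erosivity_smoothness)
    erosivity = dem.like(
        np.maximum(config.erosivity.mean + config.erosivity.sd * ero_field, 0.0)
    )

    zone_vals = _voronoi_zones(rng, shape, config.n_zones)
    farm = np.isin(lu_vals, landuse.FARMLAND_CODES)
    table = _draw_zone_table(rng, config, zone_vals, farm, dem.cell_area_ha)
    zone_grid = CategoricalGrid(
        zone_vals,
        class_table={z: f"zone_{z}" for z in range(1, config.n_zones + 1)},
        cell_size=cs,
    )
    zones = ZoneMap(zone_grid=zone_grid, table=table)

    inputs = EpochInputs(
        land_use=land_use,
        dem=dem,
        slope=slope,
        erosivity=erosivity,
        zones=zones,
        epoch="epoch_1",
    )
    inputs, cluster_truth = _calibrate_clusters(
        inputs, config.clusters, WeightConfig(), GradeScale()
    )
    truth = SceneTruth(clusters=cluster_truth, zone_params=table.copy(), config=config)
    return SyntheticScene(inputs=inputs, truth=truth)


def generate_epoch_series(
    config: SceneConfig,
    n_epochs: int = 3,
    drift: DriftSpec | None = None,
) -> tuple[list[EpochInputs], SceneTruth]:
    """A base scene repeated over epochs with the configured drift.

    Epoch 1 is the base scene; epoch k scales the drifting zones'
    fertilizer/pesticide intensities by growth^(k-1) and, if requested,
    converts a seeded random fraction of farmland to artificial land each
    step. With no drift all epochs are identical.
    """
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    drift = drift or DriftSpec()
    scene = generate_scene(config)
    base = scene.inputs
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))

    epochs = [replace(base, epoch="epoch_1")]
    lu_vals = base.land_use.values.copy()
    for k in range(2, n_epochs + 1):
        table = base.zones.table.copy()
        step = k - 1
        for zid, g in drift.fertilizer_growth.items():
            table.loc[zid, "fertilizer_kg"] *= g**step
        for zid, g in drift.pesticide_growth.items():
            table.loc[zid, "pesticide_kg"] *= g**step
        if drift.farmland_loss > 0:
            farm_idx = np.flatnonzero(np.isin(lu_vals, landuse.FARMLAND_CODES).ravel())
            n_convert = int(round(drift.farmland_loss * farm_idx.size))
            chosen = rng.choice(farm_idx, size=n_convert, replace=False)
            lu_vals.ravel()[chosen] = landuse.ARTIFICIAL
        land_use = CategoricalGrid(
            lu_vals.copy(),
            class_table=dict(landuse.LAND_CLASSES),
            cell_size=base.land_use.cell_size,
            origin=base.land_use.origin,
        )
        zones = ZoneMap(zone_grid=base.zones.zone_grid, table=table)
        epochs.append(
            replace(base, land_use=land_use, zones=zones, epoch=f"epoch_{k}")
        )
    return epochs, scene.truth
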