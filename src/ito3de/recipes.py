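"""Recipes assembling each indicator layer from raw scene inputs.

The raw inputs of one epoch are bundled in :class:`EpochInputs`: the
land-use raster, terrain layers, and the per-zone statistics table. Each
``build_indicator`` call spatializes the relevant raw quantity (zonal
dispersion, distance transform, neighborhood statistic, ...) and normalizes
it against its reference.

Zone-table columns consumed, by indicator:

- I1: ``fertilizer_kg`` (total per zone, dispersed over farmland)
- I2: ``pesticide_kg`` (idem)
- I3: ``livestock_load_ratio``, ``livestock_facility_deficiency``,
  ``livestock_scale_ratio`` (already reference-scaled ratios; Nemerow
  composite painted over the suitable-breeding mask)
- I9: ``cod_index``, ``nh3n_index``, ``tp_index`` (C/S pollution indices;
  Nemerow composite painted zone-wide)
- I10: ``runoff_modulus``
- I11: ``river_density`` (km/km2), ``lake_density`` (km2/km2)

I12 (paddy retention) needs no table column: the paddy share of farmland is
measured from the land-use raster per zone. By default the index is painted
on paddy cells, with non-paddy farmland receiving the capped (worst) value —
where paddy is absent there is nothing retaining runoff; the zone-wide
alternative is available via ``paddy_zone_wide=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landuse
from .grid import (
    Grid,
    ZoneMap,
    euclidean_distance,
    focal_statistic,
    zonal_paint,
    zonal_spread,
)
from .indicators import (
    CAP_VALUE,
    DEFAULT_K_LOOKUP,
    DEFAULT_K_REFERENCE,
    DEFAULT_SPECS,
    LAKE_DENSITY_REF,
    RIVER_DENSITY_REF,
    IndicatorLayer,
    IndicatorSpec,
    nemerow_scalar,
    normalize_negative,
    normalize_positive,
)

__all__ = ["EpochInputs", "build_indicator", "build_all_indicators"]


@dataclass
class EpochInputs:
    """Raw layers and statistics of one epoch, on one shared geometry."""

    land_use: "landuse.CategoricalGrid"
    dem: Grid
    slope: Grid  # degrees
    erosivity: Grid  # rainfall erosivity R
    zones: ZoneMap
    #: additive local perturbations of the raw intensities (planted
    #: clusters); zero grids when absent
    fertilizer_extra: Grid | None = None
    pesticide_extra: Grid | None = None
    erosivity_extra: Grid | None = None
    k_lookup: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_K_LOOKUP))
    k_reference: float = DEFAULT_K_REFERENCE
    breeding_codes: tuple[int, ...] = landuse.BREEDING_CODES
    paddy_zone_wide: bool = False
    epoch: str = ""

    def __post_init__(self) -> None:
        for name in ("dem", "slope", "erosivity"):
            self.land_use.require_same_geometry(getattr(self, name), name)
        self.land_use.require_same_geometry(self.zones.zone_grid, "zones")


def _with_extra(base: Grid, extra: Grid | None) -> Grid:
    if extra is None:
        return base
    base.require_same_geometry(extra, "local adjustment")
    vals = base.to_nan() + extra.to_nan()
    return base.from_nan(vals)


def _paddy_share(inputs: EpochInputs) -> pd.Series:
    """Paddy / farmland cell-count share per zone (NaN where no farmland)."""
    lu, zones = inputs.land_use, inputs.zones
    share = {}
    for zid in zones.zone_ids:
        zsel = zones.zone_mask(zid)
        farm = np.isin(lu.values, landuse.FARMLAND_CODES) & zsel
        n_farm = int(farm.sum())
        if n_farm == 0:
            share[zid] = np.nan
            continue
        n_paddy = int(((lu.values == landuse.PADDY) & zsel).sum())
        share[zid] = n_paddy / n_farm
    return pd.Series(share)


def build_indicator(
    ind_id: str,
    inputs: EpochInputs,
    spec: IndicatorSpec | None = None,
) -> IndicatorLayer:
    """Build one normalized indicator layer from the raw epoch inputs."""
    spec = spec or DEFAULT_SPECS[ind_id]
    lu, zones, table = inputs.land_use, inputs.zones, inputs.zones.table
    farm = landuse.farmland_mask(lu)

    def need(*cols: str) -> None:
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"{ind_id}: zone table lacks column(s) {missing}")

    if ind_id in ("I1", "I2"):
        col = "fertilizer_kg" if ind_id == "I1" else "pesticide_kg"
        extra = inputs.fertilizer_extra if ind_id == "I1" else inputs.pesticide_extra
        need(col)
        intensity = _with_extra(zonal_spread(zones, table[col], farm), extra)
        grid = normalize_positive(intensity, spec.reference)
    elif ind_id == "I3":
        cols = (
            "livestock_load_ratio",
            "livestock_facility_deficiency",
            "livestock_scale_ratio",
        )
        need(*cols)
        per_zone = {
            zid: nemerow_scalar(table.loc[zid, list(cols)].to_numpy(dtype=float))
            for zid in zones.zone_ids
        }
        breeding = lu.mask_of(*inputs.breeding_codes)
        grid = zonal_paint(zones, per_zone, mask=breeding)
        grid = grid.from_nan(np.minimum(grid.to_nan(), CAP_VALUE))
    elif ind_id == "I4":
        grid = normalize_positive(
            _with_extra(inputs.erosivity, inputs.erosivity_extra), spec.reference
        )
    elif ind_id == "I5":
        relief = focal_statistic(inputs.dem, 7, "range")
        grid = normalize_positive(relief, spec.reference)
    elif ind_id == "I6":
        label_of = lu.class_table or landuse.LAND_CLASSES
        k_vals = np.zeros(lu.shape)
        for code, label in label_of.items():
            k_vals[lu.values == code] = inputs.k_lookup.get(label, 0.0)
        grid = normalize_positive(lu.as_grid().like(k_vals), inputs.k_reference)
    elif ind_id == "I7":
        ratio = np.minimum(inputs.slope.to_nan() / spec.reference, CAP_VALUE)
        ratio = np.where(farm.values == 1, ratio, 0.0)
        grid = inputs.slope.from_nan(ratio)
    elif ind_id == "I8":
        dist = euclidean_distance(landuse.water_mask(lu))
        grid = normalize_negative(dist, spec.reference)
    elif ind_id == "I9":
        cols = ("cod_index", "nh3n_index", "tp_index")
        need(*cols)
        per_zone = {
            zid: nemerow_scalar(table.loc[zid, list(cols)].to_numpy(dtype=float))
            for zid in zones.zone_ids
        }
        grid = zonal_paint(zones, per_zone)
        grid = grid.from_nan(np.minimum(grid.to_nan(), CAP_VALUE))
    elif ind_id == "I10":
        need("runoff_modulus")
        painted = zonal_paint(zones, table["runoff_modulus"])
        grid = normalize_negative(painted, spec.reference)
    elif ind_id == "I11":
        need("river_density", "lake_density")
        combined = {
            zid: 0.5
            * (
                table.loc[zid, "river_density"] / RIVER_DENSITY_REF
                + table.loc[zid, "lake_density"] / LAKE_DENSITY_REF
            )
            for zid in zones.zone_ids
        }
        painted = zonal_paint(zones, combined)
        grid = normalize_negative(painted, spec.reference)
    elif ind_id == "I12":
        share = _paddy_share(inputs)
        idx = {
            zid: (
                min(spec.reference / p, CAP_VALUE)
                if p and not np.isnan(p)
                else CAP_VALUE
            )
            for zid, p in share.items()
        }
        if inputs.paddy_zone_wide:
            grid = zonal_paint(zones, idx)
        else:
            # paddy cells get the zone index; remaining farmland the capped
            # (worst) value — no paddy there means no retention at all;
            # non-farmland cells carry no retention indicator
            on_paddy = zonal_paint(zones, idx, mask=landuse.paddy_mask(lu))
            vals = on_paddy.to_nan()
            non_paddy_farm = (farm.values == 1) & (lu.values != landuse.PADDY)
            vals[non_paddy_farm] = CAP_VALUE
            vals[farm.values != 1] = 0.0
            grid = on_paddy.from_nan(vals)
    else:
        raise ValueError(f"unknown indicator id {ind_id!r}")

    return IndicatorLayer(spec=spec, grid=grid)


def build_all_indicators(
    inputs: EpochInputs,
    specs: dict[str, IndicatorSpec] | None = None,
) -> dict[str, IndicatorLayer]:
    """All twelve indicator layers, keyed by id."""
    specs = specs or DEFAULT_SPECS
    return {ind_id: build_indicator(ind_id, inputs, spec) for ind_id, spec in specs.items()}
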