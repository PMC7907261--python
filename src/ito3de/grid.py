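"""Raster data model and spatial primitives.

Every layer in the pipeline is carried by a :class:`Grid`: a single-band,
row-major raster with a top-left origin, square cells and a nodata sentinel.
Cell (r, c) has its center at ``origin + ((c + 0.5) * cell_size,
-(r + 0.5) * cell_size)``; all distances are cell-center to cell-center.
Layers entering one analysis must share geometry exactly — there is no
implicit resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "Grid",
    "CategoricalGrid",
    "ZoneMap",
    "GeometryError",
    "focal_statistic",
    "euclidean_distance",
    "zonal_spread",
    "zonal_paint",
    "zonal_mean",
    "area_proportions",
]

DEFAULT_NODATA = -9999.0


class GeometryError(ValueError):
    """Raised when layers that must share geometry do not."""


@dataclass
class Grid:
    """Single-band raster: float values, square cells, top-left origin.

    Parameters
    ----------
    values
        2-D float array, shape ``(nrows, ncols)``.
    cell_size
        Cell edge length in meters (> 0).
    origin
        ``(x, y)`` map coordinates of the top-left corner.
    nodata
        Sentinel marking missing cells; excluded from every statistic.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def same_geometry(self, other: "Grid | CategoricalGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "Grid | CategoricalGrid", what: str = "layer") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what}: geometry mismatch "
                f"({self.shape}@{self.cell_size} vs {other.shape}@{other.cell_size})"
            )

    # -- nodata handling --------------------------------------------------
    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def to_nan(self) -> np.ndarray:
        """Values with nodata replaced by NaN (copy)."""
        out = self.values.astype(float, copy=True)
        out[self.nodata_mask] = np.nan
        return out

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new Grid sharing this one's geometry."""
        return Grid(
            np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
        )

    def from_nan(self, values: np.ndarray) -> "Grid":
        """A new Grid with NaNs re-encoded as this grid's nodata sentinel."""
        out = np.asarray(values, dtype=float).copy()
        out[np.isnan(out)] = self.nodata
        return self.like(out)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


@dataclass
class CategoricalGrid:
    """Integer-coded raster with a class legend (land use, zones, grades)."""

    values: np.ndarray
    class_table: dict[int, str] = field(default_factory=dict)
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int64)
        if self.values.ndim != 2:
            raise ValueError("CategoricalGrid values must be 2-D")
        if self.class_table:
            present = np.unique(self.values[self.values != self.nodata])
            unknown = [int(c) for c in present if int(c) not in self.class_table]
            if unknown:
                raise ValueError(f"codes missing from class_table: {unknown}")

    nrows = Grid.nrows
    ncols = Grid.ncols
    shape = Grid.shape
    cell_area_m2 = Grid.cell_area_m2
    cell_area_ha = Grid.cell_area_ha
    same_geometry = Grid.same_geometry
    require_same_geometry = Grid.require_same_geometry
    cell_centers = Grid.cell_centers

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def mask_of(self, *codes: int) -> Grid:
        """Binary {0,1} Grid marking cells whose class is in ``codes``."""
        m = np.isin(self.values, codes) & ~self.nodata_mask
        return Grid(
            m.astype(float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=DEFAULT_NODATA,
        )

    def as_grid(self, nodata: float = DEFAULT_NODATA) -> Grid:
        vals = self.values.astype(float)
        vals[self.nodata_mask] = nodata
        return Grid(vals, cell_size=self.cell_size, origin=self.origin, nodata=nodata)


@dataclass
class ZoneMap:
    """Zone-id raster plus a per-zone attribute table.

    The table is indexed by zone id; ids present in the raster and in the
    table must coincide (administrative zones carry the tabular statistics
    that get spatialized onto their cells).
    """

    zone_grid: CategoricalGrid
    table: pd.DataFrame

    def __post_init__(self) -> None:
        grid_ids = set(
            int(z) for z in np.unique(self.zone_grid.values[~self.zone_grid.nodata_mask])
        )
        table_ids = set(int(z) for z in self.table.index)
        if grid_ids != table_ids:
            raise ValueError(
                f"zone ids in grid and table differ: grid-only={sorted(grid_ids - table_ids)}, "
                f"table-only={sorted(table_ids - grid_ids)}"
            )

    @property
    def zone_ids(self) -> list[int]:
        return [int(z) for z in self.table.index]

    def zone_mask(self, zone_id: int) -> np.ndarray:
        return self.zone_grid.values == zone_id


# ---------------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------------

_FOCAL_STATS = ("range", "mean", "min", "max")


def focal_statistic(grid: Grid, window: int, stat: str = "range") -> Grid:
    """Moving-window (neighborhood) statistic, nodata-aware.

    ``window`` is the odd edge length of the square neighborhood. Edge cells
    use the truncated window; a cell is nodata iff its whole window is nodata.
    ``stat='range'`` over a 7x7 window of a DEM is the relief-amplitude layer
    used by the terrain indicator.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if stat not in _FOCAL_STATS:
        raise ValueError(f"stat must be one of {_FOCAL_STATS}, got {stat!r}")
    if grid.values.size == 0:
        raise ValueError("empty grid")

    half = window // 2
    padded = np.pad(grid.to_nan(), half, mode="constant", constant_values=np.nan)
    win = sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        if stat == "mean":
            out = np.nanmean(win, axis=(2, 3))
        elif stat == "min":
            out = np.nanmin(win, axis=(2, 3))
        elif stat == "max":
            out = np.nanmax(win, axis=(2, 3))
        else:
            out = np.nanmax(win, axis=(2, 3)) - np.nanmin(win, axis=(2, 3))
    return grid.from_nan(out)


def euclidean_distance(mask: Grid) -> Grid:
    """Distance in meters from each cell center to the nearest source cell.

    ``mask`` is a {0,1} grid; 1-cells are sources and receive distance 0.
    """
    src = mask.values == 1
    if not src.any():
        raise ValueError("distance transform needs at least one source cell")
    dist = ndimage.distance_transform_edt(~src, sampling=mask.cell_size)
    return mask.like(dist)


def zonal_spread(
    zones: ZoneMap,
    totals: dict[int, float] | pd.Series,
    mask: Grid,
) -> Grid:
    """Disperse per-zone totals evenly over the zone's masked cells.

    Implements the "evenly dispersed in the <land-use> area" assumption:
    mask cells of zone *z* get ``totals[z] / (n_mask_cells(z) * cell_area_ha)``
    — an intensity per hectare; other cells get 0. A zone with a positive
    total but no mask cells is dropped with a warning (its cells stay 0)
    rather than spread zone-wide.
    """
    zones.zone_grid.require_same_geometry(mask, "zonal_spread mask")
    totals = pd.Series(totals, dtype=float)
    out = np.zeros(mask.shape)
    in_mask = mask.values == 1
    area_ha = mask.cell_area_ha
    dropped: list[int] = []
    for zid, total in totals.items():
        zsel = zones.zone_mask(int(zid)) & in_mask
        n = int(zsel.sum())
        if n == 0:
            if total > 0:
                dropped.append(int(zid))
            continue
        out[zsel] = total / (n * area_ha)
    if dropped:
        warnings.warn(
            f"zones with positive totals but no mask cells (values dropped): {dropped}",
            stacklevel=2,
        )
    out[mask.nodata_mask] = mask.nodata
    return mask.like(out)


def zonal_paint(
    zones: ZoneMap,
    values: dict[int, float] | pd.Series,
    mask: Grid | None = None,
    fill: float = 0.0,
) -> Grid:
    """Assign each zone's scalar value uniformly to its (optionally masked) cells.

    Unlike :func:`zonal_spread` the value is intensive — it is not divided by
    area. Cells outside the mask (or in zones without a value) get ``fill``.
    """
    values = pd.Series(values, dtype=float)
    ref = mask if mask is not None else zones.zone_grid.as_grid()
    out = np.full(ref.shape, fill, dtype=float)
    sel_mask = (mask.values == 1) if mask is not None else ~zones.zone_grid.nodata_mask
    for zid, val in values.items():
        out[zones.zone_mask(int(zid)) & sel_mask] = val
    out[zones.zone_grid.nodata_mask] = ref.nodata
    return Grid(out, cell_size=ref.cell_size, origin=ref.origin, nodata=ref.nodata)


def zonal_mean(zones: ZoneMap, grid: Grid) -> pd.Series:
    """Per-zone mean of non-nodata cells; NaN for zones fully nodata."""
    zones.zone_grid.require_same_geometry(grid, "zonal_mean grid")
    vals = grid.to_nan()
    out = {}
    for zid in zones.zone_ids:
        zvals = vals[zones.zone_mask(zid)]
        zvals = zvals[~np.isnan(zvals)]
        out[zid] = float(zvals.mean()) if zvals.size else np.nan
    return pd.Series(out, name="mean")


def area_proportions(categorical: CategoricalGrid) -> pd.Series:
    """Percentage of non-nodata area per class; sums to 100."""
    valid = categorical.values[~categorical.nodata_mask]
    if valid.size == 0:
        raise ValueError("all-nodata grid has no area to apportion")
    codes, counts = np.unique(valid, return_counts=True)
    pct = counts / valid.size * 100.0
    labels = [categorical.class_table.get(int(c), int(c)) for c in codes]
    return pd.Series(pct, index=labels, name="percent")
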