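"""Kernel density surface of at-risk cells and high-risk gathering zones.

At-risk cells (grade >= a configurable minimum) are treated as unit-weight
points at their cell centers. The density surface uses the quartic
(biweight) kernel with planar Euclidean distance,

    K(d) = 3 / (pi h^2) * (1 - d^2/h^2)^2   for d < h,  else 0,

which integrates to 1 over the plane, so the surface integrates to the
point count (away from edges). Densities are reported per km^2. The surface
is then cut into 10 equal-interval grades of [0, max]; the 10th grade is
the "high-risk gathering zone" mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid

__all__ = [
    "DensitySurface",
    "select_at_risk_cells",
    "kernel_density",
    "equal_interval_grades",
    "density_analysis",
    "gathering_zone_summary",
]

M2_PER_KM2 = 1e6


@dataclass
class DensitySurface:
    """Density grid (per km^2), its 10-grade zoning and gathering mask."""

    density: Grid
    bandwidth: float
    source_grade_min: int
    grade10: Grid
    gathering_mask: Grid


def select_at_risk_cells(grade: Grid, min_grade: int = 3) -> np.ndarray:
    """Cell-center coordinates (x, y) of all cells with grade >= min_grade.

    Returns an (n, 2) array; empty selections are allowed.
    """
    vals = grade.to_nan()
    sel = ~np.isnan(vals) & (vals >= min_grade)
    xs, ys = grade.cell_centers()
    return np.column_stack([xs[sel], ys[sel]])


def kernel_density(points: np.ndarray, bandwidth: float, geometry: Grid) -> Grid:
    """Quartic-kernel density of the points, evaluated at cell centers.

    ``points`` is (n, 2) map coordinates; ``bandwidth`` the kernel radius h
    in meters. Output is per km^2; cells farther than h from every point
    are exactly 0.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cs = geometry.cell_size
    out = np.zeros(geometry.shape)
    h2 = bandwidth**2
    norm = 3.0 / (np.pi * h2) * M2_PER_KM2
    x0, y0 = geometry.origin
    reach = int(np.ceil(bandwidth / cs)) + 1
    # accumulate each point's finite-support patch
    for px, py in points:
        c = (px - x0) / cs - 0.5
        r = (y0 - py) / cs - 0.5
        r0 = max(int(np.floor(r)) - reach, 0)
        r1 = min(int(np.ceil(r)) + reach, geometry.nrows - 1)
        c0 = max(int(np.floor(c)) - reach, 0)
        c1 = min(int(np.ceil(c)) + reach, geometry.ncols - 1)
        if r1 < r0 or c1 < c0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        dx = x0 + (cols + 0.5) * cs - px
        dy = y0 - (rows + 0.5) * cs - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u = 1.0 - d2 / h2
        patch = np.where(d2 < h2, norm * u * u, 0.0)
        out[r0 : r1 + 1, c0 : c1 + 1] += patch
    out[geometry.nodata_mask] = geometry.nodata
    return geometry.like(out)


def equal_interval_grades(density: Grid, n: int = 10) -> tuple[Grid, Grid]:
    """Cut [0, max] into n equal intervals; class n is the gathering mask.

    Class k covers ((k-1)w, kw] with w = max/n; class 1 includes 0.
    """
    vals = density.to_nan()
    finite = vals[~np.isnan(vals)]
    peak = np.nanmax(vals) if finite.size else 0.0
    if not finite.size or peak <= 0:
        raise ValueError("density surface is all zero; no intervals to cut")
    width = peak / n
    k = np.ceil(vals / width)
    k = np.clip(k, 1, n)
    grade10 = density.from_nan(k)
    mask_vals = np.where(k == n, 1.0, 0.0)
    mask_vals[np.isnan(vals)] = np.nan
    return grade10, density.from_nan(mask_vals)


def density_analysis(
    grade: Grid,
    bandwidth: float | None = None,
    min_grade: int = 3,
    n_classes: int = 10,
) -> DensitySurface:
    """End-to-end: select at-risk cells, estimate density, cut 10 grades.

    Default bandwidth is 30 cell widths (900 m at the 30 m default cell).
    """
    if bandwidth is None:
        bandwidth = 30.0 * grade.cell_size
    pts = select_at_risk_cells(grade, min_grade)
    dens = kernel_density(pts, bandwidth, grade)
    grade10, mask = equal_interval_grades(dens, n_classes)
    return DensitySurface(
        density=dens,
        bandwidth=bandwidth,
        source_grade_min=min_grade,
        grade10=grade10,
        gathering_mask=mask,
    )


def gathering_zone_summary(mask: Grid) -> pd.DataFrame:
    """Connected components of the gathering mask: centroid and area.

    Returns one row per 8-connected component with its centroid in map
    coordinates and area in km^2.
    """
    m = mask.values == 1
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    rows = []
    xs, ys = mask.cell_centers()
    for lab in range(1, n + 1):
        sel = labels == lab
        rows.append(
            {
                "zone": lab,
                "centroid_x": float(xs[sel].mean()),
                "centroid_y": float(ys[sel].mean()),
                "area_km2": float(sel.sum()) * mask.cell_area_m2 / M2_PER_KM2,
                "n_cells": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
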