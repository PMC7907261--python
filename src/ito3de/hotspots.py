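"""Getis-Ord Gi* hot/cold-spot statistic with z scores, p values and Gi_Bin.

For unit i with spatial weights w_ij (self-inclusive by convention), the
Gi* z score is

    z_i = (sum_j w_ij x_j - Xbar * W_i) /
          (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))

with W_i = sum_j w_ij, Xbar the global mean, and S the global population
standard deviation (both including unit i). p values are two-sided normal
tails, and the Gi_Bin field maps |z| past the 90/95/99% normal quantiles to
confidence classes -3..+3 (negative = cold spot), optionally after
Benjamini-Hochberg false-discovery-rate adjustment of the p values.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .grid import Grid, ZoneMap, zonal_mean

__all__ = [
    "SpatialWeights",
    "HotspotSurface",
    "build_grid_weights",
    "build_zone_weights",
    "gi_star",
    "gi_bin",
    "classify_hotspots",
    "hotspot_analysis",
]

#: Normal quantiles for the 90/95/99% two-sided confidence classes.
Z_THRESHOLDS = (1.6448536269514722, 1.959963984540054, 2.5758293035489004)
ALPHA_LEVELS = (0.10, 0.05, 0.01)


@dataclass
class SpatialWeights:
    """Sparse binary (or general nonnegative) weights among n units."""

    matrix: sparse.csr_matrix
    scheme: str
    include_self: bool = True
    unit_ids: np.ndarray | None = None  # e.g. zone ids; None for grid cells

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HotspotSurface:
    """Per-unit Gi* results."""

    x: np.ndarray
    z: np.ndarray
    p: np.ndarray
    gi_bin: np.ndarray
    labels: list[str]
    unit_ids: np.ndarray | None = None


def _band_matrix(n: int, bandwidth: int) -> sparse.csr_matrix:
    """1-D adjacency within `bandwidth` steps, including self."""
    diags = [np.ones(n - abs(k)) for k in range(-bandwidth, bandwidth + 1)]
    return sparse.diags(
        diags, offsets=list(range(-bandwidth, bandwidth + 1)), format="csr"
    )


def build_grid_weights(
    geometry: Grid,
    scheme: str = "queen",
    include_self: bool = True,
    distance_band: float | None = None,
) -> SpatialWeights:
    """Binary contiguity / distance-band weights over all grid cells.

    Units are the raster cells in row-major order. ``queen`` joins the 8
    surrounding cells, ``rook`` the 4 edge neighbors; ``fixed_distance_band``
    joins all cells whose centers lie within ``distance_band`` meters.
    """
    nr, nc = geometry.shape
    eye_r, eye_c = sparse.identity(nr, format="csr"), sparse.identity(nc, format="csr")
    if scheme == "queen":
        W = sparse.kron(_band_matrix(nr, 1), _band_matrix(nc, 1), format="csr")
    elif scheme == "rook":
        W = (
            sparse.kron(_band_matrix(nr, 1), eye_c)
            + sparse.kron(eye_r, _band_matrix(nc, 1))
            - sparse.kron(eye_r, eye_c)
        ).tocsr()
    elif scheme == "fixed_distance_band":
        if distance_band is None or distance_band <= 0:
            raise ValueError("fixed_distance_band needs a positive distance")
        from scipy.spatial import cKDTree

        xs, ys = geometry.cell_centers()
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(distance_band, output_type="ndarray")
        n = pts.shape[0]
        data = np.ones(2 * pairs.shape[0] + n)
        rows = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
        W = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not include_self:
        W = W.tolil()
        W.setdiag(0)
        W = W.tocsr()
        W.eliminate_zeros()
    return SpatialWeights(matrix=W, scheme=scheme, include_self=include_self)


def build_zone_weights(
    zones: ZoneMap, scheme: str = "queen", include_self: bool = True
) -> SpatialWeights:
    """Contiguity weights among zones, from shared raster edges/corners."""
    if scheme not in ("queen", "rook"):
        raise ValueError(f"unknown zone scheme {scheme!r}")
    ids = np.asarray(zones.zone_ids)
    index = {zid: i for i, zid in enumerate(ids)}
    vals = zones.zone_grid.values
    nod = zones.zone_grid.nodata
    pairs: set[tuple[int, int]] = set()

    def collect(a: np.ndarray, b: np.ndarray) -> None:
        sel = (a != b) & (a != nod) & (b != nod)
        for za, zb in zip(a[sel].ravel(), b[sel].ravel()):
            pairs.add((index[int(za)], index[int(zb)]))
            pairs.add((index[int(zb)], index[int(za)]))

    collect(vals[:, :-1], vals[:, 1:])
    collect(vals[:-1, :], vals[1:, :])
    if scheme == "queen":
        collect(vals[:-1, :-1], vals[1:, 1:])
        collect(vals[:-1, 1:], vals[1:, :-1])
    n = len(ids)
    rows = [p[0] for p in pairs]
    cols = [p[1] for p in pairs]
    W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    if include_self:
        W = (W + sparse.identity(n, format="csr")).tocsr()
    W.data[:] = np.minimum(W.data, 1.0)
    isolated = np.flatnonzero(np.asarray(W.sum(axis=1)).ravel() <= include_self)
    if isolated.size:
        warnings.warn(
            f"zones with no neighbors (flagged not significant): "
            f"{[int(ids[i]) for i in isolated]}",
            stacklevel=2,
        )
    return SpatialWeights(matrix=W, scheme=scheme, include_self=include_self, unit_ids=ids)


def gi_star(x: np.ndarray, W: SpatialWeights) -> tuple[np.ndarray, np.ndarray]:
    """Gi* z score and two-sided p value per unit.

    Raises on a constant field (the global variance in the denominator
    vanishes, leaving the statistic undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("Gi* needs at least 2 units")
    if W.n != n:
        raise ValueError(f"weights are for {W.n} units, data has {n}")
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)  # population sd
    if S == 0:
        raise ValueError("Gi* undefined on a constant field (zero global variance)")
    M = W.matrix
    wx = M @ x
    sw = np.asarray(M.sum(axis=1)).ravel()
    sw2 = np.asarray(M.multiply(M).sum(axis=1)).ravel()
    denom_inner = (n * sw2 - sw**2) / (n - 1)
    denom = S * np.sqrt(np.maximum(denom_inner, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (wx - xbar * sw) / denom
    z = np.where(denom > 0, z, 0.0)  # e.g. a unit whose window spans all units
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (monotone step-up)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def gi_bin(
    z: np.ndarray,
    p: np.ndarray | None = None,
    alphas: tuple[float, float, float] = ALPHA_LEVELS,
    correction: str = "none",
) -> np.ndarray:
    """Confidence classes -3..+3 from z scores (optionally FDR-corrected).

    Uncorrected: |z| past the 90/95/99% normal quantiles gives |bin| 1/2/3.
    With ``correction='fdr'`` the alpha levels are applied to BH-adjusted
    two-sided p values instead.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z scores must be finite")
    mag = np.zeros(z.shape, dtype=np.int64)
    if correction == "none":
        for level, thr in enumerate(Z_THRESHOLDS, start=1):
            mag[np.abs(z) >= thr] = level
    elif correction == "fdr":
        if p is None:
            p = 2.0 * stats.norm.sf(np.abs(z))
        p_adj = _bh_adjust(np.asarray(p, dtype=float))
        for level, alpha in enumerate(sorted(alphas, reverse=True), start=1):
            mag[p_adj <= alpha] = level
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return np.sign(z).astype(np.int64) * mag


_BIN_LABELS = {
    -3: "Cold Spot 99% Confidence",
    -2: "Cold Spot 95% Confidence",
    -1: "Cold Spot 90% Confidence",
    0: "Not Significant",
    1: "Hot Spot 90% Confidence",
    2: "Hot Spot 95% Confidence",
    3: "Hot Spot 99% Confidence",
}


def classify_hotspots(bins: np.ndarray) -> list[str]:
    """Map Gi_Bin values to their hot/cold-spot confidence labels."""
    return [_BIN_LABELS[int(b)] for b in np.asarray(bins).ravel()]


def hotspot_analysis(
    score: Grid,
    zones: ZoneMap | None = None,
    scheme: str = "queen",
    correction: str = "none",
) -> tuple[HotspotSurface, pd.DataFrame]:
    """Gi* on zone means of the score (default) or on raster cells.

    With ``zones`` the analysis units are zones carrying the zonal mean of
    the composite score — the county-scale reading. Without zones each cell
    is a unit. Returns the surface and a tidy per-unit table.
    """
    if zones is not None:
        means = zonal_mean(zones, score)
        x = means.to_numpy()
        W = build_zone_weights(zones, scheme=scheme)
        unit_ids = np.asarray(means.index)
    else:
        x = score.to_nan().ravel()
        if np.isnan(x).any():
            raise ValueError("cell-level Gi* requires a gap-free score grid")
        W = build_grid_weights(score, scheme=scheme)
        unit_ids = None
    z, p = gi_star(x, W)
    bins = gi_bin(z, p, correction=correction)
    surface = HotspotSurface(
        x=x, z=z, p=p, gi_bin=bins, labels=classify_hotspots(bins), unit_ids=unit_ids
    )
    table = pd.DataFrame(
        {
            "unit": unit_ids if unit_ids is not None else np.arange(x.size),
            "x": x,
            "z": z,
            "p": p,
            "gi_bin": bins,
            "class": surface.labels,
        }
    )
    return surface, table
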