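"""File formats and the end-to-end pipeline runner.

Grids travel as ESRI ASCII rasters (plain text, ``NODATA_value`` honored),
zone tables as CSV, configuration as YAML, and run reports as JSON. The
pipeline runs, per epoch: indicators -> dimension scores -> composite ->
grades; then the three-epoch transition cube, the kernel-density gathering
zones, and the Gi* hot spots, writing every artifact plus a run log with
the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landuse
from .density import DensitySurface, density_analysis, gathering_zone_summary
from .grid import CategoricalGrid, Grid, ZoneMap, zonal_mean
from .hotspots import hotspot_analysis
from .recipes import EpochInputs, build_all_indicators
from .scoring import GradeScale, WeightConfig, score_indicators
from .transition import build_cube, category_proportions

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_zone_table",
    "PipelineSettings",
    "run_pipeline",
    "write_epoch_inputs",
    "read_epoch_inputs",
]

logger = logging.getLogger("ito3de")

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(grid: Grid | CategoricalGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster."""
    path = Path(path)
    vals = grid.values
    integral = np.issubdtype(vals.dtype, np.integer)
    xll = grid.origin[0]
    yll = grid.origin[1] - grid.nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        fmt = "%d" if integral else "%.17g"
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, categorical: bool = False) -> Grid | CategoricalGrid:
    """Read an ESRI ASCII raster; set ``categorical`` for integer layers."""
    path = Path(path)
    header: dict[str, float] = {}
    nodata = -9999.0
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed header line {line!r}") from exc
            if key == "nodata_value":
                nodata = val
            elif key in _HEADER_KEYS:
                header[key] = val
            else:
                raise ValueError(f"{path}: unknown header key {key!r}")
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise ValueError(f"{path}: header lacks {missing}")
        vals = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {vals.shape} != header ({nrows},{ncols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    if categorical:
        return CategoricalGrid(
            vals.astype(np.int64), cell_size=cell, origin=origin, nodata=int(nodata)
        )
    return Grid(vals, cell_size=cell, origin=origin, nodata=nodata)


def read_zone_table(path: str | Path) -> pd.DataFrame:
    """Zone attribute CSV, indexed by the ``zone`` column."""
    return pd.read_csv(path, index_col="zone")


def write_epoch_inputs(inputs: EpochInputs, outdir: str | Path) -> None:
    """Write one epoch's raw layers and zone table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(inputs.land_use, outdir / "land_use.asc")
    write_ascii_grid(inputs.dem, outdir / "dem.asc")
    write_ascii_grid(inputs.slope, outdir / "slope.asc")
    write_ascii_grid(inputs.erosivity, outdir / "erosivity.asc")
    write_ascii_grid(inputs.zones.zone_grid, outdir / "zones.asc")
    inputs.zones.table.to_csv(outdir / "zone_table.csv", index_label="zone")
    for name in ("fertilizer_extra", "pesticide_extra", "erosivity_extra"):
        g = getattr(inputs, name)
        if g is not None:
            write_ascii_grid(g, outdir / f"{name}.asc")


def read_epoch_inputs(indir: str | Path, epoch: str = "") -> EpochInputs:
    """Read an epoch directory written by :func:`write_epoch_inputs`."""
    indir = Path(indir)
    lu = read_ascii_grid(indir / "land_use.asc", categorical=True)
    lu.class_table = dict(landuse.LAND_CLASSES)
    zone_grid = read_ascii_grid(indir / "zones.asc", categorical=True)
    table = read_zone_table(indir / "zone_table.csv")
    zone_grid.class_table = {int(z): f"zone_{int(z)}" for z in table.index}
    extras = {}
    for name in ("fertilizer_extra", "pesticide_extra", "erosivity_extra"):
        p = indir / f"{name}.asc"
        extras[name] = read_ascii_grid(p) if p.exists() else None
    return EpochInputs(
        land_use=lu,
        dem=read_ascii_grid(indir / "dem.asc"),
        slope=read_ascii_grid(indir / "slope.asc"),
        erosivity=read_ascii_grid(indir / "erosivity.asc"),
        zones=ZoneMap(zone_grid=zone_grid, table=table),
        epoch=epoch or indir.name,
        **extras,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineSettings:
    """Knobs of a full run; defaults are the published constants."""

    weights: WeightConfig = field(default_factory=WeightConfig)
    scale: GradeScale = field(default_factory=GradeScale)
    kde_bandwidth: float | None = None  # meters; default 30 cell widths
    kde_min_grade: int = 3
    gi_unit: str = "zone"  # zone | cell
    gi_scheme: str = "queen"
    seed: int = 0


def _config_hash(settings: PipelineSettings) -> str:
    blob = json.dumps(
        {
            "weights": asdict(settings.weights),
            "scale": asdict(settings.scale),
            "kde_bandwidth": settings.kde_bandwidth,
            "kde_min_grade": settings.kde_min_grade,
            "gi_unit": settings.gi_unit,
            "gi_scheme": settings.gi_scheme,
            "seed": settings.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    epochs: list[EpochInputs],
    outdir: str | Path,
    settings: PipelineSettings | None = None,
) -> dict:
    """Score every epoch, then transition, kernel density and Gi*.

    Returns the report dict (also written as ``report.json``); all rasters
    and tables land under ``outdir``.
    """
    settings = settings or PipelineSettings()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": _config_hash(settings),
        "seed": settings.seed,
        "epochs": {},
    }

    surfaces = []
    for inputs in epochs:
        label = inputs.epoch or f"epoch_{len(surfaces) + 1}"
        logger.info("stage=score epoch=%s", label)
        try:
            layers = build_all_indicators(inputs)
            surface, dims = score_indicators(
                layers, settings.weights, settings.scale, epoch=label
            )
        except Exception as exc:  # pragma: no cover - context wrapper
            raise RuntimeError(f"scoring failed for epoch {label}: {exc}") from exc
        surfaces.append(surface)
        write_ascii_grid(surface.A, outdir / f"A_{label}.asc")
        grade_int = CategoricalGrid(
            np.where(
                surface.grade.nodata_mask, -1, surface.grade.values
            ).astype(np.int64),
            class_table={},
            cell_size=surface.grade.cell_size,
            origin=surface.grade.origin,
            nodata=-1,
        )
        write_ascii_grid(grade_int, outdir / f"grade_{label}.asc")
        zmeans = pd.DataFrame(
            {
                "A": zonal_mean(inputs.zones, surface.A),
                **{d: zonal_mean(inputs.zones, g) for d, g in dims.items()},
            }
        )
        zmeans.to_csv(outdir / f"zonal_means_{label}.csv", index_label="zone")
        vals = surface.A.to_nan()
        report["epochs"][label] = {
            "A_min": float(np.nanmin(vals)),
            "A_max": float(np.nanmax(vals)),
            "grade_counts": {
                int(k): int(v)
                for k, v in zip(*np.unique(surface.grade.values, return_counts=True))
                if k != surface.grade.nodata
            },
        }

        # per-epoch kernel density of at-risk cells
        logger.info("stage=kde epoch=%s", label)
        try:
            dens: DensitySurface = density_analysis(
                surface.grade,
                bandwidth=settings.kde_bandwidth,
                min_grade=settings.kde_min_grade,
            )
        except ValueError as exc:
            report["epochs"][label]["kde"] = {"skipped": str(exc)}
        else:
            write_ascii_grid(dens.density, outdir / f"density_{label}.asc")
            write_ascii_grid(dens.grade10, outdir / f"density_grade10_{label}.asc")
            zones_df = gathering_zone_summary(dens.gathering_mask)
            zones_df.to_csv(outdir / f"gathering_zones_{label}.csv", index=False)
            report["epochs"][label]["kde"] = {
                "bandwidth_m": dens.bandwidth,
                "peak_per_km2": float(np.nanmax(dens.density.to_nan())),
                "n_gathering_zones": int(len(zones_df)),
            }

        # Gi* hot spots of the composite
        logger.info("stage=gistar epoch=%s", label)
        try:
            _, gi_table = hotspot_analysis(
                surface.A,
                zones=inputs.zones if settings.gi_unit == "zone" else None,
                scheme=settings.gi_scheme,
            )
        except ValueError as exc:
            report["epochs"][label]["gi_star"] = {"skipped": str(exc)}
        else:
            gi_table.to_csv(outdir / f"gi_star_{label}.csv", index=False)
            report["epochs"][label]["gi_star"] = {
                "n_hot_99": int((gi_table["gi_bin"] == 3).sum()),
                "n_cold_99": int((gi_table["gi_bin"] == -3).sum()),
            }

    if len(surfaces) == 3:
        logger.info("stage=transition")
        cube = build_cube(
            surfaces[0].grade,
            surfaces[1].grade,
            surfaces[2].grade,
            epochs=tuple(s.epoch for s in surfaces),
        )
        write_ascii_grid(cube.code, outdir / "transition_code.asc")
        write_ascii_grid(cube.category, outdir / "transition_category.asc")
        props = category_proportions(cube.category)
        props.to_csv(outdir / "transition_proportions.csv", index_label="category")
        report["transition"] = {k: float(v) for k, v in props.items()}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def load_scene_config(path: str | Path):
    """Build a :class:`~ito3de.synth.SceneConfig` from a YAML file."""
    from .synth import ClusterSpec, SceneConfig, ZoneStat

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(SceneConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scene-config keys: {sorted(unknown)}")
    if "zone_stats" in raw:
        merged = dict(SceneConfig().zone_stats)
        merged.update({k: ZoneStat(**v) for k, v in raw["zone_stats"].items()})
        raw["zone_stats"] = merged
    if "erosivity" in raw:
        raw["erosivity"] = ZoneStat(**raw["erosivity"])
    if "clusters" in raw:
        raw["clusters"] = tuple(
            ClusterSpec(center=tuple(c["center"]), radius=c["radius"], target_grade=c["target_grade"])
            for c in raw["clusters"]
        )
    return SceneConfig(**raw)
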