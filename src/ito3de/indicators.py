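"""The twelve normalized risk indicators (I1–I12).

Each indicator compares a raw layer C against a reference value E and is
dimensionless: positive-direction indices are C/E (risk grows with the raw
value), negative-direction indices are E/C (risk grows as the raw value
falls, e.g. distance to water, paddy retention). Composite sub-indices
(livestock, water quality) are combined with the Nemerow index
sqrt((mean^2 + max^2)/2), which emphasizes the worst sub-index.

Normalized values are capped at ``CAP_VALUE`` so near-zero denominators stay
finite; the cap lies above the extremely-high-risk threshold of 5.0, so
capping never demotes a grade.

Indicator inventory (dimension, direction, reference):

===  =========  =========  =================================================
id   dimension  direction  raw quantity / reference
===  =========  =========  =================================================
I1   Input      positive   fertilizer intensity, 250 kg/ha of farmland
I2   Input      positive   pesticide intensity, 2.5 kg/ha of farmland
I3   Input      positive   livestock Nemerow composite of three ratios
I4   Translate  positive   rainfall erosivity R, 100 J cm/(ha h)
I5   Translate  positive   7x7 relief amplitude of the DEM, 50 m
I6   Translate  positive   soil erodibility K by land-use class, ref. K
I7   Translate  positive   farmland slope, 15 degrees
I8   Translate  negative   distance to water, 1500 m
I9   Output     positive   COD/NH3-N/TP pollution-index Nemerow composite
I10  Output     negative   runoff generation modulus, 61.95
I11  Output     negative   water-network density vs 0.404 km/km2 (rivers)
                           and 0.025 km2/km2 (lakes), unit reference
I12  Output     negative   paddy share of farmland, 0.3339
===  =========  =========  =================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "CAP_VALUE",
    "IndicatorSpec",
    "IndicatorLayer",
    "DEFAULT_SPECS",
    "normalize_positive",
    "normalize_negative",
    "nemerow_index",
]

CAP_VALUE = 10.0
"""Upper cap for every normalized index (keeps E/C finite as C -> 0)."""


@dataclass(frozen=True)
class IndicatorSpec:
    """Static description of one indicator."""

    id: str
    dimension: str  # Input | Translate | Output
    direction: str  # positive | negative
    reference: float | None  # None for Nemerow composites (I3, I9)
    weight: float

    def __post_init__(self) -> None:
        if self.dimension not in ("Input", "Translate", "Output"):
            raise ValueError(f"bad dimension {self.dimension!r}")
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.reference is not None and self.reference <= 0:
            raise ValueError(f"reference must be positive, got {self.reference}")


@dataclass
class IndicatorLayer:
    """A normalized indicator grid together with its spec."""

    spec: IndicatorSpec
    grid: Grid


#: Directions, references and within-dimension weights of the twelve indices.
DEFAULT_SPECS: dict[str, IndicatorSpec] = {
    "I1": IndicatorSpec("I1", "Input", "positive", 250.0, 0.547),
    "I2": IndicatorSpec("I2", "Input", "positive", 2.5, 0.339),
    "I3": IndicatorSpec("I3", "Input", "positive", None, 0.114),
    "I4": IndicatorSpec("I4", "Translate", "positive", 100.0, 0.290),
    "I5": IndicatorSpec("I5", "Translate", "positive", 50.0, 0.098),
    "I6": IndicatorSpec("I6", "Translate", "positive", 0.25, 0.182),
    "I7": IndicatorSpec("I7", "Translate", "positive", 15.0, 0.267),
    "I8": IndicatorSpec("I8", "Translate", "negative", 1500.0, 0.163),
    "I9": IndicatorSpec("I9", "Output", "positive", None, 0.347),
    "I10": IndicatorSpec("I10", "Output", "negative", 61.95, 0.293),
    "I11": IndicatorSpec("I11", "Output", "negative", 1.0, 0.153),
    "I12": IndicatorSpec("I12", "Output", "negative", 0.3339, 0.207),
}

#: River / lake density references behind I11 (km/km2, km2/km2).
RIVER_DENSITY_REF = 0.404
LAKE_DENSITY_REF = 0.025

#: Default soil-erodibility K by land-use class label; configuration, not
#: survey data — magnitudes follow common USLE K tabulations by cover type.
DEFAULT_K_LOOKUP: dict[str, float] = {
    "paddy": 0.25,
    "dry_land": 0.32,
    "forest": 0.15,
    "water": 0.0,
    "artificial": 0.05,
    "other": 0.28,
}
DEFAULT_K_REFERENCE = 0.25


def normalize_positive(C: Grid, E: float, cap: float = CAP_VALUE) -> Grid:
    """Positive-direction index I = C / E, capped; nodata propagates."""
    if E <= 0:
        raise ValueError(f"reference must be positive, got {E}")
    vals = C.to_nan()
    out = np.minimum(vals / E, cap)
    return C.from_nan(out)


def normalize_negative(C: Grid, E: float, cap: float = CAP_VALUE) -> Grid:
    """Negative-direction index I = E / C, capped.

    C is clamped below at E/cap before dividing — the exact floor that
    realizes the cap, so a zero raw value (e.g. distance 0 at a water cell)
    maps to the cap instead of infinity.
    """
    if E <= 0:
        raise ValueError(f"reference must be positive, got {E}")
    vals = C.to_nan()
    floor = E / cap
    out = E / np.maximum(vals, floor)
    return C.from_nan(out)


def nemerow_index(sub_indices: list[Grid]) -> Grid:
    """Nemerow composite P = sqrt((mean^2 + max^2) / 2) per cell.

    For nonnegative sub-indices, mean <= P <= max: the composite is pulled
    toward the worst sub-index, the defining feature of the Nemerow
    comprehensive-evaluation method.
    """
    if not sub_indices:
        raise ValueError("nemerow_index needs at least one sub-index grid")
    first = sub_indices[0]
    for g in sub_indices[1:]:
        first.require_same_geometry(g, "nemerow sub-index")
    stack = np.stack([g.to_nan() for g in sub_indices])
    mean = stack.mean(axis=0)
    peak = stack.max(axis=0)
    out = np.sqrt((mean**2 + peak**2) / 2.0)
    return first.from_nan(out)


def nemerow_scalar(values: "list[float] | np.ndarray") -> float:
    """Scalar Nemerow composite of per-zone sub-indices."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("nemerow_scalar needs at least one value")
    return float(np.sqrt((arr.mean() ** 2 + arr.max() ** 2) / 2.0))
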