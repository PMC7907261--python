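"""Weighted aggregation into dimension scores and the composite risk A.

The composite risk of agricultural non-point-source pollution is the
two-level weighted sum

    A  = 0.430 A1 + 0.231 A2 + 0.339 A3
    A1 = 0.547 I1 + 0.339 I2 + 0.114 I3          (Input dimension)
    A2 = 0.290 I4 + 0.098 I5 + 0.182 I6 + 0.267 I7 + 0.163 I8   (Translate)
    A3 = 0.347 I9 + 0.293 I10 + 0.153 I11 + 0.207 I12           (Output)

with Delphi-elicited weights treated here as configuration constants. A is
classified into five grades — no / low / medium / high / extremely high
risk — at the cuts 0.7, 1.0, 3.0 and 5.0.

Missing data is strict: a cell that is nodata in any contributing indicator
is nodata in the aggregate (renormalizing the remaining weights would
silently change the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .indicators import IndicatorLayer

__all__ = [
    "WeightConfig",
    "GradeScale",
    "RiskSurface",
    "GRADE_LABELS",
    "aggregate_dimension",
    "composite",
    "grade",
    "score_indicators",
]

GRADE_LABELS: dict[int, str] = {
    1: "no_risk",
    2: "low_risk",
    3: "medium_risk",
    4: "high_risk",
    5: "extremely_high_risk",
}

_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class WeightConfig:
    """Two-level weight scheme; every level must sum to 1."""

    dimension_weights: dict[str, float] = field(
        default_factory=lambda: {"A1": 0.430, "A2": 0.231, "A3": 0.339}
    )
    indicator_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "A1": {"I1": 0.547, "I2": 0.339, "I3": 0.114},
            "A2": {"I4": 0.290, "I5": 0.098, "I6": 0.182, "I7": 0.267, "I8": 0.163},
            "A3": {"I9": 0.347, "I10": 0.293, "I11": 0.153, "I12": 0.207},
        }
    )

    def __post_init__(self) -> None:
        self._check(self.dimension_weights, "dimension weights")
        for dim, w in self.indicator_weights.items():
            self._check(w, f"indicator weights of {dim}")

    @staticmethod
    def _check(weights: dict[str, float], what: str) -> None:
        if any(v <= 0 for v in weights.values()):
            raise ValueError(f"{what}: all weights must be positive")
        total = sum(weights.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"{what}: sum {total} != 1")

    def dimension_of(self, ind_id: str) -> str:
        for dim, w in self.indicator_weights.items():
            if ind_id in w:
                return dim
        raise KeyError(ind_id)

    def flat_weight(self, ind_id: str) -> float:
        """Product of level weights: the effective weight of one indicator in A."""
        dim = self.dimension_of(ind_id)
        return self.dimension_weights[dim] * self.indicator_weights[dim][ind_id]


@dataclass(frozen=True)
class GradeScale:
    """Five-grade classification of the composite score.

    Grade 1 (no risk) on [0, t1]; 2 on (t1, t2]; 3 on (t2, t3];
    4 on (t3, t4); 5 on [t4, inf). The closed lower endpoint of grade 1 and
    the closed upper endpoint of grade 5 follow the published class
    definitions ("<= 0.7" and ">= 5.0"); interior cuts are right-closed.
    """

    thresholds: tuple[float, float, float, float] = (0.7, 1.0, 3.0, 5.0)
    labels: tuple[str, ...] = tuple(GRADE_LABELS[k] for k in range(1, 6))

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 4 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be 4 strictly increasing values")
        if len(self.labels) != 5:
            raise ValueError("exactly 5 grade labels required")

    def classify(self, a: np.ndarray) -> np.ndarray:
        t1, t2, t3, t4 = self.thresholds
        out = np.full(np.shape(a), 3, dtype=np.int64)
        a = np.asarray(a, dtype=float)
        out[a <= t2] = 2
        out[a <= t1] = 1
        out[a > t3] = 4
        out[a >= t4] = 5
        return out


@dataclass
class RiskSurface:
    """Composite score grid and its grade classification for one epoch."""

    A: Grid
    grade: "Grid"
    epoch: str = ""


def _weighted_sum(grids: dict[str, Grid], weights: dict[str, float]) -> Grid:
    if set(grids) != set(weights):
        raise ValueError(
            f"weights/ids mismatch: layers {sorted(grids)} vs weights {sorted(weights)}"
        )
    total = abs(sum(weights.values()) - 1.0)
    if total > _WEIGHT_TOL:
        raise ValueError("weights must sum to 1")
    first = next(iter(grids.values()))
    acc = np.zeros(first.shape)
    # canonical key order: results are bit-identical under layer permutation
    for key in sorted(grids):
        g = grids[key]
        first.require_same_geometry(g, key)
        acc = acc + weights[key] * g.to_nan()  # NaN in any layer -> NaN out
    return first.from_nan(acc)


def aggregate_dimension(
    layers: dict[str, IndicatorLayer] | dict[str, Grid],
    weights: dict[str, float],
) -> Grid:
    """Cellwise weighted sum of one dimension's indicator layers."""
    grids = {
        k: (v.grid if isinstance(v, IndicatorLayer) else v) for k, v in layers.items()
    }
    return _weighted_sum(grids, weights)


def composite(A1: Grid, A2: Grid, A3: Grid, config: WeightConfig | None = None) -> Grid:
    """Comprehensive risk A from the three dimension scores."""
    config = config or WeightConfig()
    return _weighted_sum({"A1": A1, "A2": A2, "A3": A3}, config.dimension_weights)


def grade(A: Grid, scale: GradeScale | None = None) -> Grid:
    """Classify the composite score into grades 1..5; nodata propagates."""
    scale = scale or GradeScale()
    vals = A.to_nan()
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite < 0).any():
        raise ValueError("composite score must be nonnegative")
    graded = scale.classify(np.nan_to_num(vals, nan=0.0)).astype(float)
    graded[np.isnan(vals)] = np.nan
    return A.from_nan(graded)


def score_indicators(
    layers: dict[str, IndicatorLayer],
    config: WeightConfig | None = None,
    scale: GradeScale | None = None,
    epoch: str = "",
) -> tuple[RiskSurface, dict[str, Grid]]:
    """Full aggregation: indicators -> dimension scores -> composite -> grades.

    Returns the risk surface and the three dimension grids (keyed A1..A3).
    """
    config = config or WeightConfig()
    dims: dict[str, Grid] = {}
    for dim, w in config.indicator_weights.items():
        sub = {i: layers[i] for i in w}
        dims[dim] = aggregate_dimension(sub, w)
    A = composite(dims["A1"], dims["A2"], dims["A3"], config)
    g = grade(A, scale)
    return RiskSurface(A=A, grade=g, epoch=epoch), dims
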