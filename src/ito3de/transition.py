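"""Spatiotemporal transition matrix of risk grades over three epochs.

Each cell's grade trajectory (g1, g2, g3), with grades 1–5, is packed into
a three-digit code B = 100*g1 + 10*g2 + g3: code 123 reads "no risk in the
first epoch, low risk in the second, medium risk in the third". Codes are
then classified into six trajectory categories:

- ``no_change_grade_k`` (k = 1..5): all three digits equal k;
- ``increase``: non-decreasing with at least one strict rise;
- ``decline``: non-increasing with at least one strict fall;
- ``fluctuation``: everything else (a rise and a fall).

The six groups partition all 125 possible trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CategoricalGrid, Grid

__all__ = [
    "TransitionCube",
    "CATEGORY_CODES",
    "encode_transition",
    "decode_transition",
    "classify_code",
    "classify_transition",
    "category_proportions",
    "transition_table",
]

#: Category legend for the change raster.
CATEGORY_CODES: dict[int, str] = {
    1: "no_change_grade_1",
    2: "no_change_grade_2",
    3: "no_change_grade_3",
    4: "no_change_grade_4",
    5: "no_change_grade_5",
    6: "increase",
    7: "decline",
    8: "fluctuation",
}

_MAX_GRADE = 9  # base-10 digit packing bound


@dataclass
class TransitionCube:
    """Three epoch grade grids with their code and category rasters."""

    grades: tuple[Grid, Grid, Grid]
    code: Grid
    category: CategoricalGrid
    epochs: tuple[str, str, str] = ("", "", "")


def _check_grades(g: Grid) -> None:
    vals = g.to_nan()
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        return
    if ((finite < 1) | (finite > 5) | (finite != np.round(finite))).any():
        raise ValueError("grade grids must hold integers in 1..5")


def encode_transition(g1: Grid, g2: Grid, g3: Grid) -> Grid:
    """Pack three epoch grades into the 3-digit code 100*g1 + 10*g2 + g3."""
    g1.require_same_geometry(g2, "epoch 2 grades")
    g1.require_same_geometry(g3, "epoch 3 grades")
    for g in (g1, g2, g3):
        _check_grades(g)
    code = 100 * g1.to_nan() + 10 * g2.to_nan() + g3.to_nan()
    return g1.from_nan(code)


def decode_transition(code: Grid) -> tuple[Grid, Grid, Grid]:
    """Recover the three grade grids from a code grid."""
    c = code.to_nan()
    return (
        code.from_nan(np.floor(c / 100)),
        code.from_nan(np.floor(c / 10) % 10),
        code.from_nan(c % 10),
    )


def classify_code(code: int) -> str:
    """Trajectory category of one 3-digit code."""
    digits = (code // 100, (code // 10) % 10, code % 10)
    if any(d < 1 or d > 5 for d in digits):
        raise ValueError(f"invalid transition code {code}")
    d1, d2, d3 = digits
    if d1 == d2 == d3:
        return f"no_change_grade_{d1}"
    nondec = d1 <= d2 <= d3
    noninc = d1 >= d2 >= d3
    if nondec:
        return "increase"
    if noninc:
        return "decline"
    return "fluctuation"


_LABEL_TO_CODE = {v: k for k, v in CATEGORY_CODES.items()}


def classify_transition(code: Grid) -> CategoricalGrid:
    """Classify every cell's code into the six trajectory categories."""
    vals = code.to_nan()
    out = np.full(code.shape, -1, dtype=np.int64)
    finite = ~np.isnan(vals)
    for c in np.unique(vals[finite]).astype(int):
        out[finite & (vals == c)] = _LABEL_TO_CODE[classify_code(int(c))]
    return CategoricalGrid(
        out,
        class_table=dict(CATEGORY_CODES),
        cell_size=code.cell_size,
        origin=code.origin,
        nodata=-1,
    )


def category_proportions(category: CategoricalGrid) -> pd.Series:
    """Percent of non-nodata area per trajectory category; sums to 100."""
    valid = category.values[~category.nodata_mask]
    if valid.size == 0:
        raise ValueError("all-nodata category grid")
    codes, counts = np.unique(valid, return_counts=True)
    pct = counts / valid.size * 100.0
    labels = [category.class_table[int(c)] for c in codes]
    return pd.Series(pct, index=labels, name="percent")


def build_cube(
    g1: Grid, g2: Grid, g3: Grid, epochs: tuple[str, str, str] = ("", "", "")
) -> TransitionCube:
    code = encode_transition(g1, g2, g3)
    return TransitionCube(
        grades=(g1, g2, g3),
        code=code,
        category=classify_transition(code),
        epochs=epochs,
    )


def transition_table() -> pd.DataFrame:
    """The full 125-row code -> category lookup, for documentation/audit."""
    rows = []
    for d1 in range(1, 6):
        for d2 in range(1, 6):
            for d3 in range(1, 6):
                code = 100 * d1 + 10 * d2 + d3
                rows.append({"code": code, "category": classify_code(code)})
    return pd.DataFrame(rows)
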