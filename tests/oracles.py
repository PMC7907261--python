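"""Independent brute-force reference implementations.

Deliberately written as plain double loops over cells/points so they share
no code path with the package: these are the oracles the vectorized
implementations are checked against.
"""

from __future__ import annotations

import math

import numpy as np


def focal_bf(values: np.ndarray, window: int, stat: str, nodata: float) -> np.ndarray:
    """Truncated-window neighborhood statistic by explicit window scan."""
    nr, nc = values.shape
    half = window // 2
    out = np.full((nr, nc), nodata, dtype=float)
    for r in range(nr):
        for c in range(nc):
            vals = []
            for rr in range(max(0, r - half), min(nr, r + half + 1)):
                for cc in range(max(0, c - half), min(nc, c + half + 1)):
                    v = values[rr, cc]
                    if v != nodata:
                        vals.append(v)
            if not vals:
                continue
            if stat == "range":
                out[r, c] = max(vals) - min(vals)
            elif stat == "mean":
                out[r, c] = sum(vals) / len(vals)
            elif stat == "min":
                out[r, c] = min(vals)
            elif stat == "max":
                out[r, c] = max(vals)
    return out


def distance_bf(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Nearest-source Euclidean distance by scanning every source cell."""
    nr, nc = mask.shape
    sources = [(r, c) for r in range(nr) for c in range(nc) if mask[r, c] == 1]
    out = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            out[r, c] = min(
                math.hypot(r - sr, c - sc) for sr, sc in sources
            ) * cell_size
    return out


def gi_star_bf(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gi* z scores from a dense weight matrix, one unit at a time."""
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar**2)
    z = np.empty(n)
    for i in range(n):
        wx = sum(weights[i, j] * x[j] for j in range(n))
        sw = sum(weights[i, j] for j in range(n))
        sw2 = sum(weights[i, j] ** 2 for j in range(n))
        denom = s * math.sqrt((n * sw2 - sw**2) / (n - 1))
        z[i] = (wx - xbar * sw) / denom
    return z


def queen_weights_bf(nr: int, nc: int, include_self: bool = True) -> np.ndarray:
    """Dense queen-contiguity weights by pairwise Chebyshev distance."""
    n = nr * nc
    W = np.zeros((n, n))
    for i in range(n):
        ri, ci = divmod(i, nc)
        for j in range(n):
            rj, cj = divmod(j, nc)
            cheb = max(abs(ri - rj), abs(ci - cj))
            if cheb == 1 or (cheb == 0 and include_self):
                W[i, j] = 1.0
    return W


def quartic_kde_bf(
    points: np.ndarray,
    bandwidth: float,
    nr: int,
    nc: int,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Quartic-kernel density (per km^2) by full point x cell double loop."""
    out = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            x = origin[0] + (c + 0.5) * cell_size
            y = origin[1] - (r + 0.5) * cell_size
            total = 0.0
            for px, py in points:
                d = math.hypot(x - px, y - py)
                if d < bandwidth:
                    u = 1.0 - (d / bandwidth) ** 2
                    total += 3.0 / (math.pi * bandwidth**2) * u * u
            out[r, c] = total * 1e6
    return out


def classify_trajectory_bf(code: int) -> str:
    """Independent trajectory predicate over the three digits."""
    d = [int(ch) for ch in f"{code:03d}"]
    rises = any(b > a for a, b in zip(d, d[1:]))
    falls = any(b < a for a, b in zip(d, d[1:]))
    if not rises and not falls:
        return f"no_change_grade_{d[0]}"
    if rises and not falls:
        return "increase"
    if falls and not rises:
        return "decline"
    return "fluctuation"
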