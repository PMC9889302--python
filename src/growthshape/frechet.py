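"""Generalized discrete Fréchet distance between sparse growth trajectories.

A trajectory is a sequence of (age, z) vertices. The distance couples the
two vertex sequences monotonically (each step advances one or both
sequences) and minimises either the maximum pairwise cost (classical
Fréchet) or the summed cost (DTW-like) over all couplings. The pairwise
cost mixes the time and z axes,

    d(p, q) = sqrt((λ·Δage)² + Δz²),

with λ (``time_scale``) converting months into z-score-comparable units.
Because the coupling may dwell on a vertex, trajectories with missing
visits or irregular schedules are compared without imputation — missing
points are simply absent from the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ShapeDistanceConfig:
    """λ (z-units per month of age mismatch) and the coupling aggregation."""

    time_scale: float = 0.1
    aggregation: str = "max"  # "max" (classical Frechet) or "sum" (DTW-like)

    def __post_init__(self):
        if self.time_scale < 0:
            raise ValueError("time_scale must be non-negative")
        if self.aggregation not in ("max", "sum"):
            raise ValueError("aggregation must be 'max' or 'sum'")


def _as_points(traj) -> tuple[list[float], list[float]]:
    t, z = traj
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = np.isfinite(t) & np.isfinite(z)
    t, z = t[keep], z[keep]
    if t.size == 0:
        raise ValueError("trajectory has no non-missing points")
    return t.tolist(), z.tolist()


def frechet_distance(a, b, cfg: ShapeDistanceConfig = ShapeDistanceConfig()) -> float:
    """Distance between trajectories ``a`` and ``b``, each ``(ages, zs)``.

    Dynamic programme over the monotone-coupling lattice; O(len(a)·len(b)).
    Symmetric; zero iff the vertex sequences coincide (given λ > 0).
    """
    ta, za = _as_points(a)
    tb, zb = _as_points(b)
    lam = cfg.time_scale
    use_max = cfg.aggregation == "max"
    n, m = len(ta), len(tb)

    # dp[j] holds the current row; plain floats keep the inner loop cheap
    prev = [0.0] * m
    curr = [0.0] * m
    for i in range(n):
        tai, zai = ta[i], za[i]
        for j in range(m):
            dt = lam * (tai - tb[j])
            dz = zai - zb[j]
            c = math.sqrt(dt * dt + dz * dz)
            if i == 0 and j == 0:
                best = 0.0 if use_max else 0.0
            elif i == 0:
                best = curr[j - 1]
            elif j == 0:
                best = prev[0]
            else:
                best = min(prev[j], prev[j - 1], curr[j - 1])
            if use_max:
                curr[j] = c if c > best else best
            else:
                curr[j] = c + best
        prev, curr = curr, prev
    return prev[m - 1]


def distance_matrix(
    trajs: Sequence, cfg: ShapeDistanceConfig = ShapeDistanceConfig()
) -> np.ndarray:
    """Symmetric pairwise distance matrix with zero diagonal.

    No triangle inequality is asserted: with ``sum`` aggregation the
    generalized distance is not a metric.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    pts = [_as_points(t) for t in trajs]
    n = len(pts)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = frechet_distance(pts[i], pts[j], cfg)
            D[i, j] = D[j, i] = d
    return D
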