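"""The occupancy index OC: normalized area of a union of equal disks.

Each dot carries a circular region of influence of radius r = d/2; the
occupancy value is the area of the union of these disks divided by its
maximum possible value n*pi*(d/2)^2 (n disjoint disks).  Overlap — i.e.
local clustering — lowers the value, which is what makes OC a predictor of
numerosity underestimation.

Two methods are provided:

* ``occupancy_analytic`` — exact.  The union boundary consists of arcs of
  the input circles; for each circle the angular intervals strictly inside
  other disks are removed and the remaining arcs are integrated with
  Green's theorem (A = 1/2 \\oint x dy - y dx).  Holes enclosed by rings of
  disks are handled automatically because every boundary arc, traversed
  counterclockwise about its own center, keeps the union on its left.
* ``occupancy_raster`` — pixel-counting on a grid, mirroring a
  draw-and-count screen-capture procedure; approximate, with error bounded
  by (perimeter x cell size).

Disks are not clipped to the stimulus aperture by default: the reference
procedure draws circles on a full canvas and counts every covered pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimgen import PointConfiguration

__all__ = ["OccupancyResult", "occupancy_analytic", "occupancy_raster", "union_of_disks_area"]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class OccupancyResult:
    value: float
    d: float
    method: str  # "analytic" | "raster"
    pattern_id: str = ""
    resolution: float | None = None  # cells per pixel, raster only


class ResolutionOverflowError(MemoryError):
    """Raster grid would exceed the configured cell budget."""


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of angular intervals (start, end), end > start, unrolled into [0, 2pi)."""
    pieces: list[tuple[float, float]] = []
    for a, b in ivals:
        w = b - a
        a %= TWO_PI
        b = a + w
        if b > TWO_PI:
            pieces.append((a, TWO_PI))
            pieces.append((0.0, b - TWO_PI))
        else:
            pieces.append((a, b))
    pieces.sort()
    merged = [list(pieces[0])]
    for a, b in pieces[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _arc_area_contribution(cx: float, cy: float, r: float, t1: float, t2: float) -> float:
    # 1/2 * integral of (x dy - y dx) along the arc t1 -> t2 (counterclockwise)
    return 0.5 * (
        r * r * (t2 - t1)
        + cx * r * (math.sin(t2) - math.sin(t1))
        - cy * r * (math.cos(t2) - math.cos(t1))
    )


def union_of_disks_area(centers: np.ndarray, r: float) -> float:
    """Exact area of the union of equal-radius disks.

    Exactly coincident centers are collapsed first (they contribute a single
    disk).  For each remaining circle, the arc strictly inside a neighboring
    disk at center distance s < 2r is the interval of half-width
    acos(s / 2r) about the direction of that neighbor.
    """
    centers = np.asarray(centers, dtype=float)
    centers = np.unique(centers, axis=0)
    k = centers.shape[0]
    if r <= 0:
        raise ValueError("r must be > 0")
    diff = centers[:, None, :] - centers[None, :, :]
    s = np.sqrt((diff**2).sum(axis=-1))
    area = 0.0
    for i in range(k):
        covered: list[tuple[float, float]] = []
        fully = False
        for j in range(k):
            if j == i:
                continue
            sij = s[i, j]
            if sij >= 2 * r:
                continue
            phi = math.atan2(centers[j, 1] - centers[i, 1], centers[j, 0] - centers[i, 0])
            beta = math.acos(sij / (2 * r))
            covered.append((phi - beta, phi + beta))
        cx, cy = centers[i]
        if not covered:
            area += math.pi * r * r
            continue
        merged = _merge_intervals(covered)
        # complement of merged within [0, 2pi)
        cursor = 0.0
        for a, b in merged:
            if a > cursor:
                area += _arc_area_contribution(cx, cy, r, cursor, a)
            cursor = max(cursor, b)
        if cursor < TWO_PI:
            area += _arc_area_contribution(cx, cy, r, cursor, TWO_PI)
    return area


def occupancy_analytic(config: PointConfiguration, d: float) -> OccupancyResult:
    """Exact occupancy: union area of radius-d/2 disks over n*pi*(d/2)^2."""
    if d <= 0:
        raise ValueError("d must be > 0")
    r = d / 2.0
    area = union_of_disks_area(config.points, r)
    return OccupancyResult(
        value=area / (config.n * math.pi * r * r),
        d=float(d),
        method="analytic",
        pattern_id=config.pattern_id,
    )


def occupancy_raster(
    config: PointConfiguration,
    d: float,
    resolution: float = 1.0,
    cell_budget: int = 100_000_000,
) -> OccupancyResult:
    """Raster occupancy: draw each disk on a shared grid and count cells.

    Cell centers sit at integer multiples of the cell size (1/resolution),
    so resolution 1 reproduces integer-pixel-center sampling.  A cell counts
    as covered when its center lies inside (or on) any disk.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    r = d / 2.0
    cell = 1.0 / resolution
    pts = config.points
    x0 = math.floor((pts[:, 0].min() - r) / cell) - 1
    x1 = math.ceil((pts[:, 0].max() + r) / cell) + 1
    y0 = math.floor((pts[:, 1].min() - r) / cell) - 1
    y1 = math.ceil((pts[:, 1].max() + r) / cell) + 1
    nx, ny = int(x1 - x0 + 1), int(y1 - y0 + 1)
    if nx * ny > cell_budget:
        raise ResolutionOverflowError(f"raster grid {nx}x{ny} exceeds budget {cell_budget}")
    grid = np.zeros((nx, ny), dtype=bool)
    rr = r * r
    span = int(math.ceil(r / cell)) + 1
    for cx, cy in pts:
        ix = int(round(cx / cell))
        iy = int(round(cy / cell))
        xs = np.arange(ix - span, ix + span + 1)
        ys = np.arange(iy - span, iy + span + 1)
        dx = xs * cell - cx
        dy = ys * cell - cy
        mask = dx[:, None] ** 2 + dy[None, :] ** 2 <= rr
        grid[xs[0] - x0 : xs[-1] - x0 + 1, ys[0] - y0 : ys[-1] - y0 + 1] |= mask
    area = grid.sum() * cell * cell
    return OccupancyResult(
        value=float(area / (config.n * math.pi * r * r)),
        d=float(d),
        method="raster",
        pattern_id=config.pattern_id,
        resolution=resolution,
    )
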