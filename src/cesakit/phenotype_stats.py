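"""Complementation-assay statistics and leaf-cell shape descriptors.

* Wilson score confidence intervals for the proportion of rescued
  transformant lines (no continuity correction by default; the corrected
  variant is available by flag).
* Two-tailed Fisher exact test of independence for 2×2 rescue tables,
  using the standard probability-mass rule (sum of hypergeometric
  probabilities of all tables, with fixed margins, no more probable than
  the observed one).
* Polygon shape descriptors for hand-traced cells: shoelace area, closed
  perimeter, and circularity 4π·A/P² (1 for a circle, → 0 for elongated
  shapes), computed on the raw vertices with no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ComplementationTable",
    "CellPolygon",
    "wilson_interval",
    "fisher_exact_two_sided",
    "polygon_shape",
]


@dataclass
class ComplementationTable:
    """Per-genotype counts of rescued lines out of all stable lines."""

    genotypes: list[str]
    n_rescued: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        self.n_rescued = np.asarray(self.n_rescued, dtype=int)
        self.n_total = np.asarray(self.n_total, dtype=int)
        if np.any(self.n_total <= 0):
            raise ValueError("n_total must be positive")
        if np.any((self.n_rescued < 0) | (self.n_rescued > self.n_total)):
            raise ValueError("need 0 ≤ n_rescued ≤ n_total")


@dataclass
class CellPolygon:
    """Ordered 2-D vertex list (µm), closed by convention."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an N×2 array")
        if self.vertices.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 vertices")


def wilson_interval(k: int, n: int, confidence: float = 0.95,
                    continuity: bool = False) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form without continuity correction by default (z = 1.959964 at
    95%); the continuity-corrected variant is available via ``continuity``.
    Bounds lie in [0, 1] and bracket k/n.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 ≤ k ≤ n and n ≥ 1")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    if not continuity:
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = center - half, center + half
        # the score bounds are exactly 0/1 at the boundary counts
        if k == 0:
            lo = 0.0
        if k == n:
            hi = 1.0
    else:
        lo = (2 * n * p + z * z - 1.0
              - z * np.sqrt(z * z - 2 - 1.0 / n + 4 * p * (n * (1 - p) + 1))
              ) / (2 * (n + z * z))
        hi = (2 * n * p + z * z + 1.0
              + z * np.sqrt(z * z + 2 - 1.0 / n + 4 * p * (n * (1 - p) - 1))
              ) / (2 * (n + z * z))
        if k == 0:
            lo = 0.0
        if k == n:
            hi = 1.0
    return max(0.0, float(lo)), min(1.0, float(hi))


def fisher_exact_two_sided(table: np.ndarray | list[list[int]]) -> float:
    """Two-tailed Fisher exact p-value for a 2×2 count table.

    A zero row or column margin leaves the table unorderable; the test is
    then defined as p = 1 (a warning-free, documented convention).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2×2 count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def _self_intersects(vertices: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return not Polygon(vertices).is_valid


def polygon_shape(polygon: CellPolygon) -> tuple[float, float, float]:
    """(area µm², perimeter µm, circularity) of a traced cell outline.

    Area by the shoelace formula (absolute value), perimeter as the closed
    polyline length, circularity = 4π·A/P².  Self-intersecting outlines
    raise.
    """
    v = polygon.vertices
    if _self_intersects(v):
        raise ValueError("polygon is self-intersecting")
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perimeter = float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())
    if perimeter == 0.0:
        raise ValueError("degenerate polygon with zero perimeter")
    circularity = 4.0 * np.pi * area / perimeter ** 2
    return area, perimeter, circularity
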