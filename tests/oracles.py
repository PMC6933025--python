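"""Independent oracles used by the test suite.

These deliberately avoid the package's own geometry code paths: the hull
oracle is a brute-force convex-combination check, the rectangle oracle is
the closed-form spherical-zone area, and the polygon-area oracle is
Monte-Carlo integration of uniform points on the sphere.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

AUTHALIC_RADIUS_KM = 6371.0072


def _in_triangle(p, a, b, c, eps: float) -> bool:
    """Inclusive point-in-triangle via signed areas."""

    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    if abs(cross(a, b, c)) <= eps:
        return False  # degenerate triangle: collinear containment is a segment test
    d1 = cross(a, b, p)
    d2 = cross(b, c, p)
    d3 = cross(c, a, p)
    has_neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    has_pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (has_neg and has_pos)


def _on_segment(p, a, b, eps: float) -> bool:
    cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    if abs(cross) > eps:
        return False
    dot = (p[0] - a[0]) * (b[0] - a[0]) + (p[1] - a[1]) * (b[1] - a[1])
    if dot < -eps:
        return False
    sq_len = (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2
    return dot <= sq_len + eps


def brute_force_hull_vertices(points, eps: float = 1e-12) -> set[tuple[float, float]]:
    """Hull vertex set by enumeration: a distinct point is a hull vertex iff
    it is not a convex combination of the other points (tested over all
    triangles and segments of the others). Exponential; use on small sets.
    """
    distinct = list(dict.fromkeys((float(x), float(y)) for x, y in points))
    vertices = set()
    for p in distinct:
        others = [q for q in distinct if q != p]
        covered = any(
            _in_triangle(p, a, b, c, eps) for a, b, c in combinations(others, 3)
        ) or any(_on_segment(p, a, b, eps) for a, b in combinations(others, 2))
        if not covered:
            vertices.add(p)
    return vertices


def zone_area_km2(lon1_deg: float, lon2_deg: float, lat1_deg: float, lat2_deg: float) -> float:
    """Closed-form spherical area of a lat-lon aligned rectangle."""
    dlon = math.radians(abs(lon2_deg - lon1_deg))
    return (
        AUTHALIC_RADIUS_KM**2
        * dlon
        * abs(math.sin(math.radians(lat2_deg)) - math.sin(math.radians(lat1_deg)))
    )


def monte_carlo_polygon_area_km2(
    ring, n_samples: int, rng: np.random.Generator
) -> float:
    """Spherical area of a lon/lat-chart polygon by uniform sampling on the
    sphere restricted to the ring's bounding box (lon uniform, sin-lat
    uniform), with planar point-in-polygon tests via matplotlib.
    """
    from matplotlib.path import Path as MplPath

    arr = np.asarray(ring, dtype=float)
    lon1, lon2 = arr[:, 0].min(), arr[:, 0].max()
    lat1, lat2 = arr[:, 1].min(), arr[:, 1].max()
    lons = rng.uniform(lon1, lon2, n_samples)
    s1, s2 = math.sin(math.radians(lat1)), math.sin(math.radians(lat2))
    lats = np.degrees(np.arcsin(rng.uniform(s1, s2, n_samples)))
    inside = MplPath(arr).contains_points(np.column_stack([lons, lats]), radius=1e-12)
    box_area = zone_area_km2(lon1, lon2, lat1, lat2)
    return box_area * inside.mean()
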