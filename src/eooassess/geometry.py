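"""Minimum convex polygon and its area on the authalic sphere.

The hull is computed in planar lon/lat coordinates, which is valid for the
sub-hemispheric extents this pipeline targets. The area of the resulting
ring is evaluated exactly on the authalic sphere (R = 6371.0072 km) by
Green's theorem, treating ring edges as straight segments in the lon/lat
chart: A = -R^2 * closed-integral of sin(phi) d(lambda). For rectangles
aligned with parallels and meridians this reduces to the closed-form
spherical-zone area R^2 * d(lambda) * (sin(phi2) - sin(phi1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

AUTHALIC_RADIUS_KM = 6371.0072

Ring = list[tuple[float, float]]


@dataclass(frozen=True)
class HullResult:
    """Hull and extent-of-occurrence area for one species under one mode.

    ``area_km2`` is ``None`` (undefined) when too few records exist to build
    a minimum convex polygon; a degenerate hull of >= 3 records has a
    defined area of 0.
    """

    n_records: int
    n_distinct: int
    hull_vertices: Ring
    area_km2: float | None

    @property
    def is_defined(self) -> bool:
        return self.area_km2 is not None


def _distinct(points: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    seen: dict[tuple[float, float], None] = {}
    for p in points:
        seen.setdefault((float(p[0]), float(p[1])), None)
    return list(seen)


def _recentre_longitudes(points: np.ndarray) -> np.ndarray:
    """Shift longitudes near their circular mean if the raw span exceeds 180°.

    Neither study region crosses the antimeridian; recentring merely keeps
    the behaviour defined for synthetic or pathological inputs.
    """
    lons = points[:, 0]
    if lons.max() - lons.min() <= 180.0:
        return points
    rad = np.radians(lons)
    mean = math.degrees(math.atan2(np.sin(rad).sum(), np.cos(rad).sum()))
    shifted = ((lons - mean + 180.0) % 360.0) - 180.0
    out = points.copy()
    out[:, 0] = shifted
    return out


def convex_hull(points: Sequence[tuple[float, float]]) -> Ring:
    """Convex hull ring (counter-clockwise) of the distinct input points.

    Degenerate inputs yield degenerate rings: a single vertex for coincident
    points, the two extreme vertices for collinear points, [] for no input.
    """
    distinct = _distinct(points)
    if not distinct:
        return []
    arr = _recentre_longitudes(np.asarray(distinct, dtype=float))
    if len(distinct) == 1:
        return [tuple(arr[0])]
    if len(distinct) == 2:
        return [tuple(arr[0]), tuple(arr[1])]
    try:
        hull = ConvexHull(arr)
    except QhullError:
        # collinear: return the two extreme points along the spread axis
        axis = int(np.argmax(arr.max(axis=0) - arr.min(axis=0)))
        order = np.argsort(arr[:, axis], kind="stable")
        return [tuple(arr[order[0]]), tuple(arr[order[-1]])]
    ring = [tuple(arr[i]) for i in hull.vertices]  # scipy returns CCW in 2-D
    return ring


def _edge_integral(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Integral of sin(phi) d(lambda) along a chart-straight edge (radians)."""
    dlon = lon2 - lon1
    if dlon == 0.0:
        return 0.0
    half_sum = 0.5 * (lat1 + lat2)
    half_diff = 0.5 * (lat2 - lat1)
    # (cos(lat1) - cos(lat2)) / (lat2 - lat1) == sin(half_sum) * sinc(half_diff)
    return dlon * math.sin(half_sum) * float(np.sinc(half_diff / math.pi))


def geodesic_area(ring: Sequence[tuple[float, float]]) -> float:
    """Area (km²) on the authalic sphere of a convex lon/lat ring.

    Degenerate rings (< 3 vertices) have zero area. Rings spanning more than
    180° of longitude are recentred first; a ring still wider than a
    hemisphere after recentring is rejected.
    """
    if len(ring) < 3:
        return 0.0
    arr = _recentre_longitudes(np.asarray(ring, dtype=float))
    lons = arr[:, 0]
    if lons.max() - lons.min() > 180.0:
        raise ValueError(
            "ring spans more than a hemisphere after recentring "
            f"(longitude span {lons.max() - lons.min():.2f}°)"
        )
    rad = np.radians(arr)
    total = 0.0
    n = len(rad)
    for i in range(n):
        lon1, lat1 = rad[i]
        lon2, lat2 = rad[(i + 1) % n]
        total += _edge_integral(lon1, lat1, lon2, lat2)
    return float(AUTHALIC_RADIUS_KM**2 * abs(total))


def eoo(
    records: Sequence,
    three_point_rule: str = "records",
) -> HullResult:
    """Extent of occurrence of a set of georeferenced records.

    Fewer than three data points leave the area undefined (the species is
    Data Deficient downstream). ``three_point_rule`` selects whether "data
    points" means records (default, the literal reading) or distinct
    coordinate pairs.
    """
    if three_point_rule not in ("records", "distinct"):
        raise ValueError(f"unknown three-point rule {three_point_rule!r}")
    points = [(r.longitude, r.latitude) for r in records]
    if any(p[0] is None or p[1] is None for p in points):
        raise ValueError("eoo requires georeferenced records only")
    distinct = _distinct(points)
    counted = len(points) if three_point_rule == "records" else len(distinct)
    ring = convex_hull(points)
    if counted < 3:
        return HullResult(
            n_records=len(points),
            n_distinct=len(distinct),
            hull_vertices=ring,
            area_km2=None,
        )
    return HullResult(
        n_records=len(points),
        n_distinct=len(distinct),
        hull_vertices=ring,
        area_km2=geodesic_area(ring),
    )


def hull_to_geojson_feature(species: str, ring: Ring) -> dict:
    """A GeoJSON Polygon feature (WGS84 lon/lat) for inspection output."""
    coords = [list(map(float, v)) for v in ring]
    if coords and coords[0] != coords[-1]:
        coords.append(coords[0])
    return {
        "type": "Feature",
        "properties": {"species": species},
        "geometry": {"type": "Polygon", "coordinates": [coords]},
    }
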