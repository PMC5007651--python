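"""Foraging-area comparison: alpha-hull area of provisioning start points
versus the null circular area implied by the farthest start point.

The alpha shape is built from the Delaunay triangulation: keep every
triangle whose circumradius is at most alpha and take the union.  The
reported hull uses the smallest alpha at which every input point lies on
or inside the union (bisection over the sorted circumradii); degenerate
configurations fall back to the convex hull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .errors import InvalidInputError
from .solar import GeoPoint
from .tracks import local_xy

__all__ = ["AreaReport", "alpha_shape", "hull_area", "null_area", "area_report"]


@dataclass(frozen=True)
class AreaReport:
    subject_id: str
    n_points: int
    hull_area_m2: float
    convex_area_m2: float
    alpha_m: float
    null_radius_m: float
    null_area_m2: float
    pct_covered: float  # 100 * hull / null
    degenerate: bool = False


def _circumradius(p0, p1, p2) -> float:
    a = math.dist(p1, p2)
    b = math.dist(p0, p2)
    c = math.dist(p0, p1)
    area2 = abs(
        (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
    )
    if area2 == 0:
        return math.inf
    return a * b * c / (2.0 * area2)


def alpha_shape(xy: np.ndarray, alpha: float):
    """Union of Delaunay triangles with circumradius <= ``alpha`` (with a
    tiny relative tolerance so equal-circumradius triangles are kept
    together despite floating-point jitter)."""
    tri = Delaunay(xy)
    cutoff = alpha * (1.0 + 1e-9) + 1e-12
    polys = []
    for simplex in tri.simplices:
        pts = xy[simplex]
        if _circumradius(*pts) <= cutoff:
            polys.append(Polygon(pts))
    if not polys:
        return Polygon()
    return unary_union(polys)


def _covers_all(shape, xy: np.ndarray) -> bool:
    if shape.is_empty:
        return False
    buffered = shape.buffer(1e-9)
    return all(buffered.covers(Point(p)) for p in xy)


def hull_area(points: Sequence[GeoPoint], origin: GeoPoint) -> dict:
    """Alpha-hull area (m^2) at the minimal covering alpha.

    Returns a dict with the alpha-shape area, the convex-hull area, the
    selected alpha, and a ``degenerate`` flag (set for < 3 points or
    collinear input, where both areas are zero).
    """
    xy = np.array([local_xy(p, origin) for p in points], dtype=float)
    if len(xy) < 3:
        return {"hull_area_m2": 0.0, "convex_area_m2": 0.0, "alpha_m": math.nan,
                "degenerate": True}
    convex = MultiPoint([tuple(p) for p in xy]).convex_hull
    if convex.geom_type != "Polygon" or convex.area < 1e-6:  # < 1 mm^2: collinear
        return {"hull_area_m2": 0.0, "convex_area_m2": 0.0, "alpha_m": math.nan,
                "degenerate": True}
    try:
        tri = Delaunay(xy)
    except QhullError:
        return {"hull_area_m2": float(convex.area), "convex_area_m2": float(convex.area),
                "alpha_m": math.inf, "degenerate": True}
    raw = sorted(
        r for s in tri.simplices if math.isfinite(r := _circumradius(*xy[s]))
    )
    radii: list = []  # dedupe within relative fp tolerance
    for r in raw:
        if not radii or r > radii[-1] * (1.0 + 1e-9):
            radii.append(r)
    if not radii:
        return {"hull_area_m2": float(convex.area), "convex_area_m2": float(convex.area),
                "alpha_m": math.inf, "degenerate": True}
    # candidate alphas are the circumradii; bisect for the smallest covering one
    lo, hi = 0, len(radii) - 1
    if not _covers_all(alpha_shape(xy, radii[hi]), xy):
        # even the full triangulation misses a point (should not happen):
        # fall back to the convex hull
        return {"hull_area_m2": float(convex.area), "convex_area_m2": float(convex.area),
                "alpha_m": math.inf, "degenerate": False}
    while lo < hi:
        mid = (lo + hi) // 2
        if _covers_all(alpha_shape(xy, radii[mid]), xy):
            hi = mid
        else:
            lo = mid + 1
    alpha = radii[lo]
    shape = alpha_shape(xy, alpha)
    return {"hull_area_m2": float(shape.area), "convex_area_m2": float(convex.area),
            "alpha_m": float(alpha), "degenerate": False, "shape": shape}


def null_area(points: Sequence[GeoPoint], burrow: GeoPoint) -> dict:
    """Circle area from the maximum burrow-to-point distance."""
    if not points:
        raise InvalidInputError("null_area requires >= 1 point")
    dists = [math.hypot(*local_xy(p, burrow)) for p in points]
    radius = max(dists)
    return {
        "null_radius_m": radius,
        "null_area_m2": math.pi * radius * radius,
        "degenerate": radius == 0.0,
    }


def _ring_to_lonlat(coords, origin: GeoPoint):
    from .tracks import inverse_local_xy as inv

    out = []
    for x, y in coords:
        gp = inv(x, y, origin)
        out.append([gp.lon_deg, gp.lat_deg])
    return out


def geojson_features(subject_id: str, points: Sequence[GeoPoint],
                     burrow: GeoPoint) -> list:
    """GeoJSON features (WGS84 lon/lat) for a subject's alpha hull and null
    circle."""
    h = hull_area(points, burrow)
    nl = null_area(points, burrow)
    features = []
    shape = h.get("shape")
    if shape is not None and not shape.is_empty:
        geoms = [shape] if shape.geom_type == "Polygon" else list(shape.geoms)
        for g in geoms:
            features.append({
                "type": "Feature",
                "properties": {"subject_id": subject_id, "kind": "alpha_hull",
                               "area_m2": h["hull_area_m2"], "alpha_m": h["alpha_m"]},
                "geometry": {"type": "Polygon",
                             "coordinates": [_ring_to_lonlat(g.exterior.coords, burrow)]},
            })
    if nl["null_radius_m"] > 0:
        circle = Point(0.0, 0.0).buffer(nl["null_radius_m"], quad_segs=32)
        features.append({
            "type": "Feature",
            "properties": {"subject_id": subject_id, "kind": "null_circle",
                           "area_m2": nl["null_area_m2"],
                           "radius_m": nl["null_radius_m"]},
            "geometry": {"type": "Polygon",
                         "coordinates": [_ring_to_lonlat(circle.exterior.coords, burrow)]},
        })
    return features


def area_report(subject_id: str, points: Sequence[GeoPoint], burrow: GeoPoint) -> AreaReport:
    h = hull_area(points, burrow)
    nl = null_area(points, burrow)
    degenerate = h["degenerate"] or nl["degenerate"]
    pct = 100.0 * h["hull_area_m2"] / nl["null_area_m2"] if nl["null_area_m2"] > 0 else math.nan
    return AreaReport(
        subject_id=subject_id,
        n_points=len(points),
        hull_area_m2=h["hull_area_m2"],
        convex_area_m2=h["convex_area_m2"],
        alpha_m=h["alpha_m"],
        null_radius_m=nl["null_radius_m"],
        null_area_m2=nl["null_area_m2"],
        pct_covered=pct,
        degenerate=degenerate,
    )
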