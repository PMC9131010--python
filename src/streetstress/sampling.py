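"""Sample-point placement along road networks and view-request enumeration.

The collection protocol places acquisition points every 50 m along the road
network and, at each point, requests four square street-view images (one
per compass heading 0/90/180/270) with a 90 degree field of view, a 6 degree
pitch to emulate eye level, and a 640 px frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .synthetic import RoadNetwork

DEFAULT_HEADINGS = (0.0, 90.0, 180.0, 270.0)
DEFAULT_FOV = 90.0
DEFAULT_PITCH = 6.0
DEFAULT_SIZE = 640


def points_along_network(
    network: RoadNetwork, interval: float = 50.0, deduplicate: bool = False
) -> pd.DataFrame:
    """Points at arc-lengths 0, interval, 2*interval, ... along each segment.

    The spacing is half-open [0, L): a segment's far endpoint is never
    emitted, which avoids doubled points at shared junctions. Ids follow
    traversal order. Duplicate coordinates across segments are retained
    unless ``deduplicate`` is set.
    """
    if not isinstance(network, RoadNetwork):
        raise TypeError("points_along_network requires a RoadNetwork, not point data")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if not network.segments:
        raise ValueError("empty network")
    xs, ys = [], []
    for seg in network.segments:
        line = LineString(seg)
        distances = np.arange(0.0, line.length, interval)
        if len(distances) == 0:  # zero-length segment: emit its start
            distances = np.array([0.0])
        for d in distances:
            p = line.interpolate(float(d))
            xs.append(p.x)
            ys.append(p.y)
    out = pd.DataFrame({"x": xs, "y": ys})
    if deduplicate:
        out = out.drop_duplicates(ignore_index=True)
    out.insert(0, "id", np.arange(len(out)))
    out["district"] = "unassigned"
    return out


def enumerate_view_requests(
    points: pd.DataFrame,
    headings=DEFAULT_HEADINGS,
    fov: float = DEFAULT_FOV,
    pitch: float = DEFAULT_PITCH,
    size: int = DEFAULT_SIZE,
) -> pd.DataFrame:
    """One view request per (point, heading); |result| = |points| x |headings|."""
    headings = [float(h) % 360.0 for h in headings]
    if not headings:
        raise ValueError("headings must be non-empty")
    if fov <= 0 or size <= 0:
        raise ValueError("fov and size must be positive")
    ids = points["id"].to_numpy() if len(points) else np.array([], int)
    return pd.DataFrame(
        {
            "point_id": np.repeat(ids, len(headings)),
            "heading": np.tile(headings, len(ids)),
            "fov": fov,
            "pitch": pitch,
            "size": size,
        }
    )


def _clean_polygon(coords) -> Polygon:
    """Collapse consecutive duplicate vertices; require >= 3 distinct ones."""
    pts = [tuple(map(float, c)) for c in coords]
    if len(pts) > 1 and pts[0] == pts[-1]:
        pts = pts[:-1]
    cleaned = [pts[0]]
    for p in pts[1:]:
        if p != cleaned[-1]:
            cleaned.append(p)
    if len(set(cleaned)) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    poly = Polygon(cleaned)
    if not poly.is_valid:
        raise ValueError("malformed (self-intersecting) polygon")
    return poly


def assign_districts(points: pd.DataFrame, polygons) -> pd.DataFrame:
    """Label each point with the first polygon that contains it.

    ``polygons`` is an ordered sequence of ``(name, polygon)`` pairs (or a
    dict), where each polygon is a shapely Polygon or a coordinate ring.
    Containment includes the boundary, and the first polygon tested wins —
    a deterministic tie-break for points exactly on shared edges. Points in
    no polygon are labeled ``"unassigned"``.
    """
    if isinstance(polygons, dict):
        polygons = list(polygons.items())
    prepared = []
    for name, poly in polygons:
        if not isinstance(poly, Polygon):
            poly = _clean_polygon(poly)
        else:
            _clean_polygon(list(poly.exterior.coords))
        prepared.append((name, poly))
    labels = []
    for x, y in points[["x", "y"]].itertuples(index=False):
        pt = Point(x, y)
        for name, poly in prepared:
            if poly.covers(pt):
                labels.append(name)
                break
        else:
            labels.append("unassigned")
    out = points.copy()
    out["district"] = labels
    return out


def drop_excluded(points: pd.DataFrame, excluded_ids) -> pd.DataFrame:
    """Remove points on a user-supplied exclusion list (unavailable imagery)."""
    excluded = set(excluded_ids)
    return points[~points["id"].isin(excluded)].reset_index(drop=True)
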