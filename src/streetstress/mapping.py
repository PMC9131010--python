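"""Stress-level classification and spatial aggregation.

Scores are cut into k natural-breaks classes by the exact Fisher–Jenks
dynamic program (minimizing total within-class sum of squared deviations),
grouped 2-2-2 into Low/Medium/High tiers when k = 6, binned to a pointy-top
hexagonal grid, averaged per administrative district, and summarized as
per-tier element-composition profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import CLASS_NAMES

#: Fig-13-style radar vocabulary, in canonical class names
#: (walls, buildings, sky, vegetation, roads, grass, sidewalks, auto).
RADAR_ELEMENTS = ("wall", "building", "sky", "vegetation", "road", "terrain",
                  "sidewalk", "car")

TIERS = ("Low", "Medium", "High")


def tier_of_level(level: int, k: int = 6) -> str:
    """Map a level to its tier: 2-2-2 grouping for k=6, 1-1-1 for k=3."""
    if k == 6:
        return TIERS[(level - 1) // 2]
    if k == 3:
        return TIERS[level - 1]
    raise ValueError("tier grouping defined for k = 6 or k = 3 only")


@dataclass
class BreaksClassification:
    """k ascending classes over a score range.

    ``boundaries`` are the k-1 upper bounds (class maxima) of all classes but
    the last; ``low`` and ``high`` delimit the envelope of classifiable
    values. A value belongs to the first class whose upper bound covers it.
    """

    k: int
    boundaries: np.ndarray
    low: float
    high: float

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, float)
        if len(self.boundaries) != self.k - 1:
            raise ValueError("expected k-1 boundaries")
        if (np.diff(self.boundaries) <= 0).any():
            raise ValueError("boundaries must be strictly ascending")

    def class_ranges(self) -> list[tuple[float, float]]:
        edges = [self.low, *self.boundaries, self.high]
        return [(edges[i], edges[i + 1]) for i in range(self.k)]


def jenks_breaks(values, k: int) -> BreaksClassification:
    """Exact Fisher–Jenks natural breaks via dynamic programming.

    Runs on the distinct values weighted by multiplicity, so equal values
    are never split across classes; O(k n^2) in the number of distinct
    values. Requires at least k distinct values.
    """
    values = np.asarray(values, float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, counts = np.unique(values, return_counts=True)
    m = len(uniq)
    if m < k:
        raise ValueError(f"k={k} exceeds the {m} distinct values")
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    cs = np.concatenate([[0.0], np.cumsum(counts * uniq)])
    cs2 = np.concatenate([[0.0], np.cumsum(counts * uniq**2)])

    def seg_cost(j, i):
        # within-class SSE of distinct values j..i (inclusive), weighted
        w = cw[i + 1] - cw[j]
        s = cs[i + 1] - cs[j]
        return (cs2[i + 1] - cs2[j]) - s * s / w

    idx = np.arange(m)
    cost = np.full((k, m), np.inf)
    back = np.zeros((k, m), dtype=int)
    cost[0] = seg_cost(0, idx)
    for c in range(1, k):
        for i in range(c, m):
            js = np.arange(c, i + 1)
            cand = cost[c - 1][js - 1] + seg_cost(js, i)
            best = int(np.argmin(cand))
            cost[c, i] = cand[best]
            back[c, i] = js[best]
    # backtrack the start index of each class
    starts = np.empty(k, dtype=int)
    i = m - 1
    for c in range(k - 1, 0, -1):
        starts[c] = back[c, i]
        i = starts[c] - 1
    starts[0] = 0
    boundaries = uniq[starts[1:] - 1]  # class maxima of all but the last class
    return BreaksClassification(k=k, boundaries=boundaries,
                                low=float(uniq[0]), high=float(uniq[-1]))


def classify(values, breaks: BreaksClassification) -> np.ndarray:
    """Assign each score its 1-based level (first class whose upper bound covers it).

    Values outside the [low, high] envelope are clamped into the end classes
    with a warning; classification is total.
    """
    values = np.asarray(values, float).ravel()
    outside = (values < breaks.low) | (values > breaks.high)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} value(s) outside the break envelope; "
            "clamped to the end classes",
            stacklevel=2,
        )
    return np.searchsorted(breaks.boundaries, values, side="left") + 1


def level_table(values, breaks: BreaksClassification) -> pd.DataFrame:
    """Level/count/percentage table with tier shares (k = 6 layout)."""
    levels = classify(values, breaks)
    n = len(levels)
    rows = []
    ranges = breaks.class_ranges()
    for lv in range(1, breaks.k + 1):
        count = int((levels == lv).sum())
        tier = tier_of_level(lv, breaks.k)
        rows.append(
            {
                "level": lv,
                "tier": tier,
                "score_low": ranges[lv - 1][0] if lv == 1 else float(breaks.boundaries[lv - 2]),
                "score_high": ranges[lv - 1][1],
                "count": count,
                "percent": 100.0 * count / n,
            }
        )
    table = pd.DataFrame(rows)
    table["tier_percent"] = table.groupby("tier")["percent"].transform("sum")
    return table


# ---------------------------------------------------------------------------
# hexagonal binning (pointy-top, axial coordinates)

_SQRT3 = np.sqrt(3.0)


def _axial_center(q, r, radius, origin):
    x = origin[0] + radius * _SQRT3 * (np.asarray(q) + np.asarray(r) / 2.0)
    y = origin[1] + radius * 1.5 * np.asarray(r)
    return x, y


def _cube_round(qf, rf):
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


_AXIAL_NEIGHBORS = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
)


def hex_bin(points: pd.DataFrame, scores, radius: float) -> tuple[pd.DataFrame, np.ndarray]:
    """Bin points to a pointy-top hexagonal grid and average scores per cell.

    The grid is anchored at the data bounding-box min corner; each point is
    assigned to the nearest cell center (Euclidean), boundary ties resolved
    to the lexicographically smaller (q, r). Empty cells are omitted.

    Returns (cells, assignment): ``cells`` has axial coordinates, center,
    member count and mean score; ``assignment`` holds each point's row index
    into ``cells``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xy = points[["x", "y"]].to_numpy(float)
    scores = np.asarray(scores, float)
    origin = xy.min(axis=0)
    rel = xy - origin
    qf = (_SQRT3 / 3.0 * rel[:, 0] - rel[:, 1] / 3.0) / radius
    rf = (2.0 / 3.0 * rel[:, 1]) / radius
    q0, r0 = _cube_round(qf, rf)
    # nearest-center with explicit tie-break over the candidate cell and its ring
    cand_q = q0[:, None] + _AXIAL_NEIGHBORS[:, 0]
    cand_r = r0[:, None] + _AXIAL_NEIGHBORS[:, 1]
    cx, cy = _axial_center(cand_q, cand_r, radius, origin)
    d2 = (cx - xy[:, [0]]) ** 2 + (cy - xy[:, [1]]) ** 2
    d2r = np.round(d2, 9)  # tolerate float jitter at exact boundaries
    best = np.array(
        [
            min(range(7), key=lambda j: (d2r[i, j], cand_q[i, j], cand_r[i, j]))
            for i in range(len(xy))
        ]
    )
    q = cand_q[np.arange(len(xy)), best]
    r = cand_r[np.arange(len(xy)), best]
    keys = pd.DataFrame({"q": q, "r": r, "score": scores})
    grouped = keys.groupby(["q", "r"], sort=True)["score"].agg(["size", "mean"])
    cells = grouped.reset_index().rename(columns={"size": "n", "mean": "mean_score"})
    ccx, ccy = _axial_center(cells["q"], cells["r"], radius, origin)
    cells["cx"] = ccx
    cells["cy"] = ccy
    cells["radius"] = radius
    index = {(qq, rr): i for i, (qq, rr) in enumerate(zip(cells["q"], cells["r"]))}
    assignment = np.array([index[(qq, rr)] for qq, rr in zip(q, r)])
    return cells, assignment


def hex_cell_polygon(cx: float, cy: float, radius: float) -> list[tuple[float, float]]:
    """Vertex ring of a pointy-top hexagon (for GeoJSON export)."""
    angles = np.deg2rad([90, 150, 210, 270, 330, 30])
    return [(cx + radius * np.cos(a), cy + radius * np.sin(a)) for a in angles]


def district_means(points: pd.DataFrame, scores) -> pd.DataFrame:
    """Mean score per district, ranked descending; 'unassigned' reported last."""
    if "district" not in points.columns:
        raise ValueError("points carry no district labels")
    df = pd.DataFrame({"district": points["district"].to_numpy(), "score": np.asarray(scores, float)})
    labeled = df[df["district"] != "unassigned"]
    if labeled.empty:
        raise ValueError("no labeled points")
    means = (
        labeled.groupby("district")["score"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_score", "size": "n"})
        .sort_values("mean_score", ascending=False, ignore_index=True)
    )
    means["rank"] = np.arange(1, len(means) + 1)
    unassigned = df[df["district"] == "unassigned"]
    if len(unassigned):
        extra = pd.DataFrame(
            [{"district": "unassigned", "mean_score": unassigned["score"].mean(),
              "n": len(unassigned), "rank": pd.NA}]
        )
        means = pd.concat([means, extra], ignore_index=True)
    return means


def tier_profiles(compositions: pd.DataFrame, tiers) -> pd.DataFrame:
    """Mean element coverage per stress tier (Low/Medium/High) plus counts.

    An empty tier is reported with count 0 and undefined (NaN) means.
    """
    tiers = np.asarray(tiers)
    if len(tiers) != len(compositions):
        raise ValueError("compositions and tiers misaligned")
    rows = []
    for tier in TIERS:
        mask = tiers == tier
        row = {"tier": tier, "n": int(mask.sum())}
        for name in CLASS_NAMES:
            row[name] = float(compositions.loc[mask, name].mean()) if mask.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def radar_rows(compositions: pd.DataFrame) -> pd.DataFrame:
    """Per-image 8-element rows (radar-chart vocabulary) from compositions."""
    out = compositions[["point_id", *RADAR_ELEMENTS]].copy()
    return out
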