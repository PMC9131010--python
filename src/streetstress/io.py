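"""Readers and writers for the pipeline's tabular and geospatial artifacts.

Tables are UTF-8 comma-separated CSV with a header row; geometries are
RFC 7946 GeoJSON whose coordinates are planar meters (declared in a
``crs_note`` property, since GeoJSON itself presumes geographic axes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Polygon, mapping, shape

from .mapping import hex_cell_polygon
from .spatial import SpatialWeights
from .synthetic import RoadNetwork

CRS_NOTE = "planar coordinates in meters (projected); not lon/lat"


def load_table(path, required=None, numeric=None) -> pd.DataFrame:
    """Read a CSV, check required columns, coerce numeric columns.

    Unknown columns are preserved. A missing required column raises an
    error naming it; an unparseable cell raises with its (1-based, data)
    row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    for col in required or []:
        if col not in table.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    for col in numeric or []:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path.name}: unparseable value in column {col!r}, row {row}")
        table[col] = coerced
    return table


def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# GeoJSON


def _feature_collection(features) -> dict:
    return {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": features}


def write_network_geojson(network: RoadNetwork, path) -> Path:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(LineString(seg)),
            "properties": {"segment_id": i},
        }
        for i, seg in enumerate(network.segments)
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_feature_collection(features)))
    return path


def read_network_geojson(path) -> RoadNetwork:
    """Load LineString/MultiLineString features as a road network."""
    data = json.loads(Path(path).read_text())
    segments = []
    for feat in data["features"]:
        geom = shape(feat["geometry"])
        if isinstance(geom, LineString):
            segments.append(np.asarray(geom.coords, float))
        elif isinstance(geom, MultiLineString):
            segments.extend(np.asarray(g.coords, float) for g in geom.geoms)
        else:
            raise ValueError(f"unsupported geometry {feat['geometry']['type']} in network")
    if not segments:
        raise ValueError("no line features in network file")
    allpts = np.vstack(segments)
    extent = (*allpts.min(axis=0), *allpts.max(axis=0))
    return RoadNetwork(segments=segments, extent=extent)


def write_districts_geojson(districts, path) -> Path:
    """``districts``: ordered (name, shapely Polygon) pairs."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"name": name},
        }
        for name, poly in districts
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_feature_collection(features)))
    return path


def read_districts_geojson(path) -> list[tuple[str, Polygon]]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        geom = shape(feat["geometry"])
        name = feat.get("properties", {}).get("name", f"district_{len(out)}")
        if isinstance(geom, Polygon):
            out.append((name, geom))
        elif isinstance(geom, MultiPolygon):
            out.extend((name, g) for g in geom.geoms)
        else:
            raise ValueError(f"unsupported geometry {feat['geometry']['type']} in districts")
    return out


def write_hex_geojson(cells: pd.DataFrame, path) -> Path:
    """Hexagonal cells with their mean scores as Polygon features."""
    features = []
    for _, c in cells.iterrows():
        ring = hex_cell_polygon(c["cx"], c["cy"], c["radius"])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Polygon(ring)),
                "properties": {
                    "q": int(c["q"]),
                    "r": int(c["r"]),
                    "n": int(c["n"]),
                    "mean_score": float(c["mean_score"]),
                },
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_feature_collection(features)))
    return path


# ---------------------------------------------------------------------------
# weights and sessions


def write_weights_csv(w: SpatialWeights, path) -> Path:
    """Sparse triplet CSV with a commented header recording the build."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coo = w.matrix.tocoo()
    with path.open("w") as fh:
        fh.write(
            f"# threshold={w.threshold} metric={w.metric} "
            f"standardization={w.standardization} n={w.n}\n"
        )
        fh.write("i,j,w\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{float(v)!r}\n")
    return path


def read_weights_csv(path) -> SpatialWeights:
    path = Path(path)
    header = path.open().readline().strip().lstrip("# ")
    meta = dict(kv.split("=") for kv in header.split())
    table = pd.read_csv(path, comment="#")
    n = int(meta["n"])
    from scipy import sparse

    rows = table["i"].to_numpy(int)
    cols = table["j"].to_numpy(int)
    matrix = sparse.csr_matrix(
        (table["w"].to_numpy(float), (rows, cols)), shape=(n, n)
    )
    binary = sparse.csr_matrix((np.ones(len(table)), (rows, cols)), shape=(n, n))
    threshold = None if meta["threshold"] == "None" else float(meta["threshold"])
    counts = np.diff(binary.indptr)
    return SpatialWeights(
        matrix=matrix,
        binary=binary,
        threshold=threshold,
        metric=meta["metric"],
        standardization=meta["standardization"],
        isolates=np.flatnonzero(counts == 0),
    )


def write_session_jsonl(session, path) -> Path:
    """One JSON line per presented image, plus a trailing summary line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for rec in session.records.to_dict("records"):
            fh.write(json.dumps({"rater_id": session.rater_id, **rec}, default=float) + "\n")
        fh.write(
            json.dumps(
                {"rater_id": session.rater_id, "interventions": session.interventions,
                 "n_records": len(session.records)}
            )
            + "\n"
        )
    return path
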