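"""Visual-element composition of street scenes.

A scene's composition is the vector of per-class pixel-coverage fractions
produced by semantic segmentation over the 19 Cityscapes training classes,
plus a void fraction for unlabeled pixels. Fractions are non-negative and,
together with void, sum to one.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 19 Cityscapes training classes, in label-id order (ids 0..18).
CLASS_NAMES: tuple[str, ...] = (
    "road",
    "sidewalk",
    "building",
    "wall",
    "fence",
    "pole",
    "traffic_light",
    "traffic_sign",
    "vegetation",
    "terrain",
    "sky",
    "person",
    "rider",
    "car",
    "truck",
    "bus",
    "train",
    "motorcycle",
    "bicycle",
)

N_CLASSES = len(CLASS_NAMES)

#: Label id used for unlabeled (void) pixels in label rasters.
VOID_LABEL = 255

#: Survey vocabulary -> Cityscapes class name.
CLASS_ALIASES: dict[str, str] = {"grass": "terrain", "auto": "car", "tree": "vegetation"}

#: Columns of a composition table: point id, 19 class fractions, void.
COMPOSITION_COLUMNS: tuple[str, ...] = ("point_id", *CLASS_NAMES, "void")


def canonical_class(name: str) -> str:
    """Resolve a class name or survey alias to the canonical Cityscapes name."""
    key = name.strip().lower().replace(" ", "_")
    key = CLASS_ALIASES.get(key, key)
    if key not in CLASS_NAMES:
        raise ValueError(f"unknown visual-element class: {name!r}")
    return key


def fractions_from_label_raster(raster: np.ndarray) -> pd.Series:
    """Per-class coverage fractions of an integer label raster.

    Parameters
    ----------
    raster : ndarray of int
        Grid of class ids in 0..18, or ``VOID_LABEL`` for unlabeled pixels.

    Returns
    -------
    Series indexed by the 19 class names plus ``"void"``; values sum to 1.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty label raster")
    flat = raster.ravel()
    valid = (flat >= 0) & (flat < N_CLASSES)
    void = flat == VOID_LABEL
    bad = ~(valid | void)
    if bad.any():
        raise ValueError(f"invalid label ids in raster: {np.unique(flat[bad])}")
    counts = np.bincount(flat[valid], minlength=N_CLASSES).astype(float)
    values = np.append(counts, void.sum()) / flat.size
    return pd.Series(values, index=[*CLASS_NAMES, "void"])


def aggregate_views(views: pd.DataFrame | Sequence[pd.Series]) -> pd.Series:
    """Average the compositions of the (up to four) views of one point.

    Views are the per-heading images taken at a sample point; with equal
    pixel counts per view, the unweighted mean of per-view fractions equals
    the fraction computed on the stitched panorama.

    ``views`` is a DataFrame of composition rows (or a sequence of Series);
    if a ``point_id`` column is present all rows must share it.
    """
    if not isinstance(views, pd.DataFrame):
        views = pd.DataFrame(list(views))
    if len(views) == 0 or len(views) > 4:
        raise ValueError("expected 1-4 views of one point")
    out = {}
    if "point_id" in views.columns:
        ids = views["point_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"views mix point_ids {sorted(ids)}")
        out["point_id"] = ids[0]
    for col in (*CLASS_NAMES, "void"):
        out[col] = float(views[col].mean())
    return pd.Series(out)


def aggregate_views_by_point(views: pd.DataFrame) -> pd.DataFrame:
    """Group a view-level composition table by point_id and average each group."""
    means = views.groupby("point_id", sort=True)[[*CLASS_NAMES, "void"]].mean()
    return means.reset_index()


def validate_compositions(table: pd.DataFrame, *, atol: float = 1e-9) -> None:
    """Check the simplex invariants of a composition table; raise on violation."""
    cols = [*CLASS_NAMES, "void"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"composition table missing columns: {missing}")
    frac = table[cols].to_numpy(float)
    if (frac < -atol).any():
        raise ValueError("negative coverage fraction")
    total = frac.sum(axis=1)
    if not np.allclose(total, 1.0, atol=max(atol, 1e-6)):
        raise ValueError("fractions plus void must sum to 1")


def element_summary(compositions: pd.DataFrame, top_k: int | None = 8) -> pd.DataFrame:
    """Descriptive statistics (mean/max/min/population SD) per element.

    Classes are ranked by descending mean coverage, ties broken by class id;
    only the ``top_k`` highest-mean classes are retained (all if None).
    """
    if len(compositions) == 0:
        raise ValueError("no compositions to summarize")
    rows = []
    for class_id, name in enumerate(CLASS_NAMES):
        x = compositions[name].to_numpy(float)
        rows.append(
            {
                "element": name,
                "class_id": class_id,
                "mean": x.mean(),
                "max": x.max(),
                "min": x.min(),
                "sd": x.std(ddof=0),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(["mean", "class_id"], ascending=[False, True], kind="stable")
    if top_k is not None:
        table = table.head(top_k)
    return table.reset_index(drop=True)
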