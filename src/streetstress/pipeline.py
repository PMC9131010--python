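"""End-to-end orchestration: simulate -> sample -> compose -> score ->
spatial -> map -> regress, with a reproducibility manifest.

A single global seed derives independent per-stage seeds by stable hashing
of the stage name, so any stage can be re-run in isolation. Every artifact
is a new file; the manifest records versions, per-stage seeds, row counts,
and SHA-256 checksums, and identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import __version__
from .composition import CLASS_NAMES
from .io import (
    write_hex_geojson,
    write_network_geojson,
    write_session_jsonl,
    write_table,
    write_weights_csv,
)
from .mapping import district_means, hex_bin, jenks_breaks, level_table, tier_of_level, tier_profiles
from .regression import DEFAULT_PREDICTORS, StressRegression
from .sampling import assign_districts, points_along_network
from .scoring import consensus_scores, evaluate_holdout, run_scoring_session
from .spatial import LISA, Moran, build_weights
from .synthetic import (
    RaterProfile,
    generate_latent_stress,
    generate_road_network,
    generate_scene_compositions,
)

STAGES = ("simulate", "sample", "compose", "score", "spatial", "map", "regress")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed from the single global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters behind one validated object."""

    outdir: str = "streetstress_run"
    seed: int = 0
    stages: tuple = STAGES
    # simulate
    n_segments: int = 40
    extent: tuple = (0.0, 0.0, 2000.0, 2000.0)
    # sample
    interval: float = 50.0
    synthetic_districts: bool = True
    # score
    n_raters: int = 2
    n_init: int = 50
    err_thresh: float = 10.0
    streak: int = 6
    rater_noise_sd: float = 5.0
    forest_params: dict = field(default_factory=lambda: dict(
        n_trees=150, mtry=6, min_leaf=2, max_depth=None))
    train_frac: float = 0.667
    # latent truth
    spatial_rho: float = 0.7
    latent_noise_sd: float = 5.0
    # spatial
    threshold: float | str = "auto"
    metric: str = "manhattan"
    standardization: str = "row"
    n_perm: int = 199
    alpha: float = 0.05
    # map
    k: int = 6
    hex_radius: float | None = 100.0
    # regress
    predictors: tuple = DEFAULT_PREDICTORS

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if not (0 <= self.spatial_rho < 1):
            raise ValueError("spatial_rho must be in [0, 1)")
        if "map" in self.stages and (self.hex_radius is None or self.hex_radius <= 0):
            raise ValueError("map stage requires a positive hex_radius")
        if "score" in self.stages and self.n_raters < 1:
            raise ValueError("score stage requires n_raters >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write all artifacts.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "config": {**asdict(config), "stages": list(config.stages)},
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "rows": {},
    }
    seeds = manifest["stage_seeds"]
    state: dict = {}

    def need(stage: str, key: str):
        if key not in state:
            raise RuntimeError(f"stage '{stage}' requires '{key}' from an earlier stage")
        return state[key]

    current = "setup"
    try:
        current = "simulate"
        if "simulate" in config.stages:
            network = generate_road_network(config.n_segments, config.extent,
                                            seed=seeds["simulate"])
            state["network"] = network
            files.append(write_network_geojson(network, out / "network.geojson"))

        current = "sample"
        if "sample" in config.stages:
            points = points_along_network(need("sample", "network"), config.interval)
            if config.synthetic_districts:
                xmin, ymin, xmax, ymax = config.extent
                xm, ym = (xmin + xmax) / 2, (ymin + ymax) / 2
                quads = [
                    ("NW", Polygon([(xmin, ym), (xm, ym), (xm, ymax), (xmin, ymax)])),
                    ("NE", Polygon([(xm, ym), (xmax, ym), (xmax, ymax), (xm, ymax)])),
                    ("SW", Polygon([(xmin, ymin), (xm, ymin), (xm, ym), (xmin, ym)])),
                    ("SE", Polygon([(xm, ymin), (xmax, ymin), (xmax, ym), (xm, ym)])),
                ]
                points = assign_districts(points, quads)
            state["points"] = points
            manifest["rows"]["points"] = len(points)
            files.append(write_table(points, out / "points.csv"))

        current = "compose"
        if "compose" in config.stages:
            compositions = generate_scene_compositions(
                need("compose", "points"), seed=seeds["compose"]
            )
            state["compositions"] = compositions
            manifest["rows"]["compositions"] = len(compositions)
            files.append(write_table(compositions, out / "compositions.csv"))

        # weights are needed by both the latent truth and the spatial stage
        current = "weights"
        if {"score", "spatial"} & set(config.stages):
            points = need("weights", "points")
            weights = build_weights(points, threshold=config.threshold,
                                    metric=config.metric,
                                    standardization=config.standardization)
            state["weights"] = weights
            files.append(write_weights_csv(weights, out / "weights.csv"))

        current = "score"
        if "score" in config.stages:
            compositions = need("score", "compositions")
            latent = generate_latent_stress(
                compositions,
                spatial_rho=config.spatial_rho,
                noise_sd=config.latent_noise_sd,
                weights=state["weights"],
                seed=seeds["simulate"] + 1,
            )
            state["latent"] = latent
            files.append(
                write_table(
                    pd.DataFrame({"point_id": compositions["point_id"], "score": latent}),
                    out / "latent_scores.csv",
                )
            )
            raters = RaterProfile.population(
                config.n_raters, noise_sd=config.rater_noise_sd, seed=seeds["score"]
            )
            sessions = []
            for i, rater in enumerate(raters):
                session = run_scoring_session(
                    rater,
                    compositions,
                    n_init=config.n_init,
                    err_thresh=config.err_thresh,
                    streak=config.streak,
                    forest_params=config.forest_params,
                    seed=seeds["score"] + i,
                )
                sessions.append(session)
                files.append(write_session_jsonl(session, out / f"session_{session.rater_id}.jsonl"))
            consensus = consensus_scores(sessions)
            state["scores"] = consensus.to_numpy()
            manifest["rows"]["scores"] = len(consensus)
            manifest["interventions"] = {s.rater_id: s.interventions for s in sessions}
            files.append(
                write_table(consensus.reset_index(), out / "consensus_scores.csv")
            )
            X = compositions[list(CLASS_NAMES)].to_numpy(float)
            report = evaluate_holdout(
                X, state["scores"], train_frac=config.train_frac,
                forest_params=config.forest_params, seed=seeds["score"] + 1000,
            )
            manifest["accuracy"] = asdict(report)

        current = "spatial"
        if "spatial" in config.stages:
            scores = need("spatial", "scores")
            weights = state["weights"]
            moran = Moran(scores, weights)
            lisa = LISA(scores, weights, n_perm=config.n_perm, alpha=config.alpha,
                        seed=seeds["spatial"])
            summary = moran.summary().to_dict()
            manifest["moran"] = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                                 for k, v in summary.items()}
            (out / "moran.json").write_text(json.dumps(manifest["moran"], indent=2))
            files.append(out / "moran.json")
            files.append(
                write_table(lisa.to_frame(need("spatial", "points")["id"]), out / "lisa.csv")
            )
            manifest["lisa_quadrants"] = lisa.quadrant_counts()

        current = "map"
        if "map" in config.stages:
            scores = need("map", "scores")
            points = need("map", "points")
            breaks = jenks_breaks(scores, config.k)
            table = level_table(scores, breaks)
            files.append(write_table(table, out / "level_table.csv"))
            levels = np.searchsorted(breaks.boundaries, scores, side="left") + 1
            tiers = np.array([tier_of_level(int(l), config.k) for l in levels])
            state["tiers"] = tiers
            cells, _ = hex_bin(points, scores, config.hex_radius)
            files.append(write_hex_geojson(cells, out / "hex_cells.geojson"))
            files.append(write_table(district_means(points, scores), out / "district_means.csv"))
            if "compositions" in state:
                files.append(
                    write_table(tier_profiles(state["compositions"], tiers),
                                out / "tier_profiles.csv")
                )
            manifest["rows"]["hex_cells"] = len(cells)

        current = "regress"
        if "regress" in config.stages:
            compositions = need("regress", "compositions")
            data = compositions.copy()
            data["score"] = need("regress", "scores")
            results = StressRegression(data, predictors=config.predictors).fit()
            files.append(write_table(results.coefficient_table(), out / "regression.csv"))
            manifest["regression"] = {
                "r2": results.rsquared,
                "adj_r2": results.rsquared_adj,
                "dw": results.dw,
                "n": results.nobs,
            }
    except Exception as exc:  # annotate failures with the stage context
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    manifest["checksums"] = {p.name: _checksum(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
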