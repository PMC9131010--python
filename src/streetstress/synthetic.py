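"""Synthetic streetscapes, stress fields, and raters.

Every downstream stage of the pipeline — composition, scoring, spatial
statistics, mapping, regression — is exercisable without imagery by
generating data with the statistical structure the analysis assumes:

* compositional 19-class element vectors drawn per scene archetype from a
  Dirichlet distribution (the simplest parametric family on the simplex
  matching coverage-fraction semantics), with a void component absorbing
  the residual;
* a latent stress field that is linear in element coverages plus a
  spatially autocorrelated simultaneous-autoregressive (SAR) residual,
  clipped to the 0-100 scoring scale;
* raters whose subjective scores are noisy linear functions of a scene's
  composition, consuming a seeded noise stream;
* integer label rasters realizing a composition exactly (largest-remainder
  apportionment), the inverse of fraction extraction, for round-trip tests.

Ground-truth stress coefficients default to walls and buildings raising
stress and sky, vegetation, road, grass/terrain, sidewalk and cars lowering
it, so that sign-recovery tests downstream are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .composition import CLASS_NAMES, N_CLASSES, VOID_LABEL

#: Signed ground-truth score weights (score units per unit coverage).
DEFAULT_STRESS_COEFFICIENTS: dict[str, float] = {
    "wall": 80.0,
    "building": 60.0,
    "sky": -40.0,
    "vegetation": -30.0,
    "road": -25.0,
    "terrain": -20.0,
    "sidewalk": -15.0,
    "car": -10.0,
}

DEFAULT_INTERCEPT = 55.0


def stress_coefficient_vector(coefficients: dict[str, float] | None = None) -> np.ndarray:
    """Expand a {class: weight} dict to a 19-vector in class-id order."""
    coefficients = DEFAULT_STRESS_COEFFICIENTS if coefficients is None else coefficients
    vec = np.zeros(N_CLASSES)
    for name, value in coefficients.items():
        vec[CLASS_NAMES.index(name)] = value
    return vec


@dataclass
class RoadNetwork:
    """Planar road network: polyline segments (meters) within an extent."""

    segments: list[np.ndarray]
    extent: tuple[float, float, float, float]

    def __post_init__(self):
        for seg in self.segments:
            if len(seg) < 2:
                raise ValueError("every segment needs at least 2 vertices")
            if not np.isfinite(seg).all():
                raise ValueError("non-finite segment coordinates")

    def total_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum() for seg in self.segments)
        )


@dataclass
class SceneArchetype:
    """A scene type (residential, park, ...) as Dirichlet concentrations.

    ``concentration`` holds 19 positive shape parameters over the element
    classes; ``void_concentration`` is the shape of the unlabeled residual.
    Larger relative concentration means larger expected coverage.
    """

    name: str
    concentration: np.ndarray
    void_concentration: float = 1.0

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        if self.concentration.shape != (N_CLASSES,):
            raise ValueError(f"concentration must have length {N_CLASSES}")
        if (self.concentration <= 0).any() or self.void_concentration <= 0:
            raise ValueError("concentrations must be positive")

    @classmethod
    def from_dict(cls, name: str, weights: dict[str, float], base: float = 0.05,
                  void_concentration: float = 1.0) -> "SceneArchetype":
        conc = np.full(N_CLASSES, base)
        for cls_name, w in weights.items():
            conc[CLASS_NAMES.index(cls_name)] = w
        return cls(name, conc, void_concentration)


def default_archetypes() -> dict[str, SceneArchetype]:
    """Four stock scene archetypes spanning calm to stressful streetscapes."""
    return {
        a.name: a
        for a in [
            SceneArchetype.from_dict(
                "residential",
                {"building": 10, "road": 8, "sky": 6, "wall": 2, "sidewalk": 2,
                 "vegetation": 2, "car": 1.5},
            ),
            SceneArchetype.from_dict(
                "commercial",
                {"building": 14, "road": 7, "sky": 4, "car": 3, "sidewalk": 3,
                 "wall": 1.5, "person": 1, "vegetation": 0.8},
            ),
            SceneArchetype.from_dict(
                "park",
                {"vegetation": 12, "terrain": 5, "sky": 8, "road": 4, "sidewalk": 2},
            ),
            SceneArchetype.from_dict(
                "arterial",
                {"road": 14, "sky": 9, "car": 3, "building": 4, "vegetation": 2,
                 "sidewalk": 1.5},
            ),
        ]
    }


def generate_road_network(n_segments: int, extent, seed: int | None = None) -> RoadNetwork:
    """Random jittered polylines inside ``extent`` (xmin, ymin, xmax, ymax)."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    span = min(xmax - xmin, ymax - ymin)
    segments = []
    for _ in range(n_segments):
        start = rng.uniform([xmin, ymin], [xmax, ymax])
        angle = rng.uniform(0, 2 * np.pi)
        n_vert = int(rng.integers(2, 6))
        step = rng.uniform(0.1, 0.3) * span
        pts = [start]
        for _ in range(n_vert - 1):
            angle += rng.normal(0, 0.4)
            pts.append(pts[-1] + step * np.array([np.cos(angle), np.sin(angle)]))
        seg = np.clip(np.array(pts), [xmin, ymin], [xmax, ymax])
        segments.append(seg)
    return RoadNetwork(segments=segments, extent=(xmin, ymin, xmax, ymax))


def grid_points(nx: int, ny: int, spacing: float = 50.0, origin=(0.0, 0.0)) -> pd.DataFrame:
    """Regular nx-by-ny point lattice, a convenient stand-in sampling frame."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing + origin[0],
                         np.arange(ny) * spacing + origin[1])
    return pd.DataFrame(
        {"id": np.arange(nx * ny), "x": xs.ravel(), "y": ys.ravel(),
         "district": "unassigned"}
    )


def generate_scene_compositions(
    points: pd.DataFrame,
    archetypes: dict[str, SceneArchetype] | None = None,
    assignment=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one 19-class composition per point from its archetype.

    ``assignment`` maps points to archetype names: a sequence aligned with
    ``points``, a dict {point id: name}, or None to assign archetypes in
    spatially contiguous vertical bands (so scene type itself is spatially
    structured, as in a real city).
    """
    archetypes = archetypes if archetypes is not None else default_archetypes()
    rng = np.random.default_rng(seed)
    ids = points["id"].to_numpy()
    names = list(archetypes)
    if assignment is None:
        x = points["x"].to_numpy(float)
        edges = np.quantile(x, np.linspace(0, 1, len(names) + 1)[1:-1])
        labels = np.array(names)[np.searchsorted(edges, x)]
    elif isinstance(assignment, dict):
        missing = [i for i in ids if i not in assignment]
        if missing:
            raise ValueError(f"points without archetype assignment: {missing[:5]}")
        labels = np.array([assignment[i] for i in ids])
    else:
        labels = np.asarray(assignment)
        if len(labels) != len(ids):
            raise ValueError("assignment length must match points")
    rows = np.empty((len(ids), N_CLASSES + 1))
    for k, label in enumerate(labels):
        arch = archetypes[label]
        alpha = np.append(arch.concentration, arch.void_concentration)
        rows[k] = rng.dirichlet(alpha)
    out = pd.DataFrame(rows, columns=[*CLASS_NAMES, "void"])
    out.insert(0, "point_id", ids)
    out["archetype"] = labels
    return out


def generate_latent_stress(
    compositions: pd.DataFrame,
    coefficients=None,
    intercept: float = DEFAULT_INTERCEPT,
    spatial_rho: float = 0.7,
    noise_sd: float = 5.0,
    weights=None,
    seed: int | None = None,
) -> np.ndarray:
    """Latent stress scores: linear in composition + SAR residual, clipped.

    score_i = clip(intercept + beta . composition_i + u_i, 0, 100) with
    u = (I - rho*W)^-1 eps, eps ~ N(0, noise_sd^2), on the row-standardized
    weights ``weights``. rho=0 reduces u to white noise; noise_sd=0 gives
    the deterministic linear limit. Clipping is applied last.
    """
    if not (0 <= spatial_rho < 1):
        raise ValueError("spatial_rho must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    beta = (
        np.asarray(coefficients, float)
        if isinstance(coefficients, (np.ndarray, list, tuple))
        else stress_coefficient_vector(coefficients)
    )
    frac = compositions[list(CLASS_NAMES)].to_numpy(float)
    if beta.shape != (N_CLASSES,):
        raise ValueError(f"coefficients must have length {N_CLASSES}")
    mean = intercept + frac @ beta
    n = len(mean)
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        u = np.zeros(n)
    else:
        eps = rng.normal(0, noise_sd, n)
        if spatial_rho == 0:
            u = eps
        else:
            if weights is None:
                raise ValueError("spatial_rho > 0 requires a weights matrix")
            if weights.n != n:
                raise ValueError("weights and compositions size mismatch")
            a = sparse.eye(n, format="csc") - spatial_rho * sparse.csc_matrix(weights.matrix)
            u = splu(a).solve(eps)
    return np.clip(mean + u, 0.0, 100.0)


@dataclass
class RaterProfile:
    """A simulated volunteer: noisy linear scorer of scene compositions.

    Sequential :meth:`rate` calls consume the rater's seeded noise stream,
    so a session is reproducible given the profile. :meth:`reset` rewinds
    the stream.
    """

    coefficients: np.ndarray
    intercept: float
    noise_sd: float = 5.0
    seed: int | None = None
    rater_id: str = "rater"
    _rng: np.random.Generator = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape != (N_CLASSES,):
            raise ValueError(f"coefficients must have length {N_CLASSES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def rate(self, composition) -> float:
        """Score one composition on the 0-100 scale (clipped after noise)."""
        if isinstance(composition, pd.Series):
            frac = composition[list(CLASS_NAMES)].to_numpy(float)
        else:
            frac = np.asarray(composition, float)[:N_CLASSES]
        if (frac < -1e-9).any() or frac.sum() > 1 + 1e-6:
            raise ValueError("invalid composition")
        score = self.intercept + frac @ self.coefficients
        if self.noise_sd > 0:
            score += self._rng.normal(0, self.noise_sd)
        return float(np.clip(score, 0.0, 100.0))

    @classmethod
    def population(
        cls,
        n_raters: int,
        coefficients=None,
        intercept: float = DEFAULT_INTERCEPT,
        noise_sd: float = 5.0,
        between_rater_sd: float = 5.0,
        seed: int | None = None,
    ) -> list["RaterProfile"]:
        """A panel of raters sharing the ground truth up to idiosyncrasies.

        Each rater perturbs the shared coefficient vector and intercept by
        Gaussian offsets (scale ``between_rater_sd`` on the intercept, a
        proportional 10% jitter on coefficients), emulating subjective
        variation around a common perception.
        """
        rng = np.random.default_rng(seed)
        base = (
            np.asarray(coefficients, float)
            if isinstance(coefficients, (np.ndarray, list, tuple))
            else stress_coefficient_vector(coefficients)
        )
        raters = []
        for k in range(n_raters):
            coefs = base * (1 + 0.1 * rng.normal(size=N_CLASSES))
            inter = intercept + between_rater_sd * rng.normal()
            raters.append(
                cls(
                    coefficients=coefs,
                    intercept=float(inter),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                    rater_id=f"rater_{k:02d}",
                )
            )
        return raters


def render_label_raster(
    composition, width: int, height: int, seed: int | None = None
) -> np.ndarray:
    """Realize a composition as an integer label raster.

    Pixel counts per class follow largest-remainder apportionment of
    width*height pixels (ties broken by class id), so each class fraction is
    reproduced within one pixel; residual pixels are void. ``seed`` shuffles
    pixel placement only and never affects the counts.
    """
    if width < 1 or height < 1:
        raise ValueError("raster must have at least one pixel")
    if isinstance(composition, pd.Series):
        frac = composition[list(CLASS_NAMES)].to_numpy(float)
    else:
        frac = np.asarray(composition, float)[:N_CLASSES]
    total = width * height
    # apportion over 19 classes + void so every share is within one pixel
    shares = np.append(frac, max(0.0, 1.0 - frac.sum()))
    quota = shares / shares.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    remainders = quota - np.floor(quota)
    order = np.lexsort((np.arange(len(shares)), -remainders))  # ties: low id
    counts[order[:short]] += 1
    class_ids = np.append(np.arange(N_CLASSES), VOID_LABEL)
    labels = np.empty(total, dtype=np.int32)
    pos = 0
    for cls_id, cnt in zip(class_ids, counts):
        labels[pos : pos + cnt] = cls_id
        pos += cnt
    if seed is not None:
        np.random.default_rng(seed).shuffle(labels)
    return labels.reshape(height, width)
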