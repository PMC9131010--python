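"""Spatial autocorrelation of perceived-stress scores.

Implements fixed-distance-band spatial weights under the Manhattan metric
with row standardization, global Moran's I with an analytic or permutation
Z-test, Moran scatter data, neighbor-count histograms, and Local Indicators
of Spatial Association (LISA) with conditional-permutation significance and
HH/HL/LH/LL quadrant labels.

Notation
--------
For scores :math:`x_1..x_n` with deviations :math:`d_i = x_i - \\bar x` and
weights :math:`w_{ij}`,

.. math::

    I = \\frac{n}{S_0} \\cdot
        \\frac{\\sum_i \\sum_j w_{ij} d_i d_j}{\\sum_i d_i^2},
    \\qquad
    I_i = \\frac{d_i}{S^2} \\sum_j w_{ij} d_j,
    \\quad S^2 = \\tfrac{1}{n} \\sum_i d_i^2,

with :math:`S_0 = \\sum_{ij} w_{ij}`. With row-standardized weights and no
isolates :math:`S_0 = n`, so the global statistic collapses to the classic
ratio-of-cross-products form. Under the null, :math:`E(I) = -1/(n-1)`; the
variance is available under the normality or randomization assumption, or
by permutation. The local statistics satisfy
:math:`\\sum_i I_i = S_0 \\cdot I` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import cdist
from scipy.stats import norm


def manhattan_distance(a, b) -> float:
    """City-block distance |xa - xb| + |ya - yb| between two planar points."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    return float(np.abs(a - b).sum())


_METRICS = {"manhattan": "cityblock", "euclidean": "euclidean"}


def _pairwise(xy: np.ndarray, metric: str, block: int = 1024):
    """Yield (row_slice, distance_block) over pairwise distances, chunked."""
    m = _METRICS[metric]
    for start in range(0, len(xy), block):
        stop = min(start + block, len(xy))
        yield slice(start, stop), cdist(xy[start:stop], xy, metric=m)


def min_neighbor_threshold(points, metric: str = "manhattan") -> float:
    """Smallest distance band giving every point at least one neighbor.

    This is the maximum, over points, of the distance to the nearest *other*
    point. Duplicate coordinates contribute a nearest-neighbor distance of 0.
    """
    xy = _as_xy(points)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least two points")
    worst = 0.0
    for rows, d in _pairwise(xy, metric):
        np.fill_diagonal(d[:, rows], np.inf)
        worst = max(worst, float(d.min(axis=1).max()))
    return worst


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(points, float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array or a DataFrame with x, y")
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    return xy


@dataclass
class SpatialWeights:
    """Sparse spatial weights with the neighbor relation kept separately.

    ``matrix`` holds the (possibly row-standardized) weights w_ij as CSR;
    ``binary`` holds the pre-standardization 0/1 neighbor relation, which is
    symmetric under a symmetric metric. ``s0`` is the post-standardization
    sum of all weights (= n when row-standardized with no isolates).
    """

    matrix: sparse.csr_matrix
    binary: sparse.csr_matrix
    threshold: float | None = None
    metric: str = "manhattan"
    standardization: str = "row"
    isolates: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    @property
    def s1(self) -> float:
        w = self.matrix
        sym = w + w.T
        return 0.5 * float(sym.multiply(sym).sum())

    @property
    def s2(self) -> float:
        w = self.matrix
        totals = np.asarray(w.sum(axis=1)).ravel() + np.asarray(w.sum(axis=0)).ravel()
        return float((totals**2).sum())

    def neighbor_counts(self) -> np.ndarray:
        """Per-point neighbor count under the pre-standardization relation."""
        return np.diff(self.binary.indptr)

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag: weighted average of each point's neighbors."""
        return self.matrix @ np.asarray(values, float)

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.binary.indices[self.binary.indptr[i] : self.binary.indptr[i + 1]]

    @classmethod
    def from_arrays(
        cls,
        rows,
        cols,
        n: int,
        *,
        standardization: str = "row",
        threshold: float | None = None,
        metric: str = "manhattan",
    ) -> "SpatialWeights":
        """Build weights from explicit neighbor pairs (binary relation)."""
        data = np.ones(len(rows), float)
        binary = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        binary.setdiag(0)
        binary.eliminate_zeros()
        matrix = _standardize(binary, standardization)
        counts = np.diff(binary.indptr)
        return cls(
            matrix=matrix,
            binary=binary,
            threshold=threshold,
            metric=metric,
            standardization=standardization,
            isolates=np.flatnonzero(counts == 0),
        )


def _standardize(binary: sparse.csr_matrix, standardization: str) -> sparse.csr_matrix:
    if standardization not in ("row", "none"):
        raise ValueError("standardization must be 'row' or 'none'")
    matrix = binary.astype(float).copy()
    if standardization == "row":
        sums = np.asarray(matrix.sum(axis=1)).ravel()
        scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
        matrix = sparse.diags(scale) @ matrix
        matrix = sparse.csr_matrix(matrix)
    return matrix


def build_weights(
    points,
    threshold: float | str = "auto",
    metric: str = "manhattan",
    standardization: str = "row",
) -> SpatialWeights:
    """Fixed-distance-band weights: w = 1 within ``threshold`` (inclusive), 0 outside.

    ``threshold='auto'`` uses :func:`min_neighbor_threshold`, the smallest band
    giving every point at least one neighbor. Under an explicit threshold,
    isolated points are flagged and a warning is issued; if *all* points are
    isolated the band is unusable and an error is raised.
    """
    xy = _as_xy(points)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least two points")
    if metric not in _METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    auto = isinstance(threshold, str)
    if auto:
        if threshold != "auto":
            raise ValueError("threshold must be a number or 'auto'")
        threshold = min_neighbor_threshold(xy, metric)
    threshold = float(threshold)
    rows_all, cols_all = [], []
    for rows, d in _pairwise(xy, metric):
        np.fill_diagonal(d[:, rows], np.inf)
        r, c = np.nonzero(d <= threshold)
        rows_all.append(r + rows.start)
        cols_all.append(c)
    w = SpatialWeights.from_arrays(
        np.concatenate(rows_all),
        np.concatenate(cols_all),
        n,
        standardization=standardization,
        threshold=threshold,
        metric=metric,
    )
    if len(w.isolates) == n:
        raise ValueError("threshold leaves every point isolated")
    if len(w.isolates) and not auto:
        warnings.warn(
            f"{len(w.isolates)} point(s) have no neighbor within {threshold} m",
            stacklevel=2,
        )
    return w


def neighbor_count_histogram(w: SpatialWeights) -> dict[int, int]:
    """Histogram {neighbor count: number of points}; counts sum to n."""
    counts = np.bincount(w.neighbor_counts())
    return {int(k): int(v) for k, v in enumerate(counts) if v > 0}


def _deviations(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, float).ravel()
    d = values - values.mean()
    if np.allclose(d, 0):
        raise ValueError("constant values: spatial autocorrelation undefined")
    return d


class Moran:
    """Global Moran's I with analytic or permutation inference.

    Parameters
    ----------
    values : array-like
        Scores, one per point of the weights.
    weights : SpatialWeights
    variance : {'randomization', 'normality', 'permutation'}
        Null model for VAR(I). The randomization assumption (the default,
        and the default of desktop GIS spatial-autocorrelation tools)
        conditions on the observed values; normality assumes i.i.d. Gaussian
        draws; 'permutation' estimates the null by shuffling values.
    n_perm, seed : permutation settings (used when variance='permutation').

    Attributes: ``I``, ``E_I``, ``VAR_I``, ``Z``, ``p`` (two-sided), ``n``.
    """

    def __init__(
        self,
        values,
        weights: SpatialWeights,
        variance: str = "randomization",
        n_perm: int = 999,
        seed: int | None = None,
    ):
        d = _deviations(values)
        w = weights
        if len(d) != w.n:
            raise ValueError("values and weights size mismatch")
        self.n = n = len(d)
        self.variance_mode = variance
        self.I = float(n * (d @ w.lag(d)) / (w.s0 * (d @ d)))
        self.E_I = -1.0 / (n - 1)
        s0, s1, s2 = w.s0, w.s1, w.s2
        if variance == "normality":
            var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - self.E_I**2
        elif variance == "randomization":
            b2 = n * (d**4).sum() / (d @ d) ** 2
            num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
                (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
            )
            var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - self.E_I**2
        elif variance == "permutation":
            rng = np.random.default_rng(seed)
            sims = np.empty(n_perm)
            denom = d @ d
            for k in range(n_perm):
                p = d[rng.permutation(n)]
                sims[k] = n * (p @ w.lag(p)) / (w.s0 * denom)
            self.sim_I = sims
            var = float(sims.var(ddof=1))
        else:
            raise ValueError(f"unknown variance mode {variance!r}")
        self.VAR_I = float(var)
        self.Z = (self.I - self.E_I) / np.sqrt(self.VAR_I)
        if variance == "permutation":
            exceed = int((np.abs(sims - sims.mean()) >= abs(self.I - sims.mean())).sum())
            self.p = (exceed + 1) / (n_perm + 1)
        else:
            self.p = float(2 * norm.sf(abs(self.Z)))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "I": self.I,
                "E_I": self.E_I,
                "VAR_I": self.VAR_I,
                "Z": self.Z,
                "p": self.p,
                "n": self.n,
                "variance_mode": self.variance_mode,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Moran(I={self.I:.6f}, Z={self.Z:.4f}, p={self.p:.4g}, n={self.n})"


def global_morans_i(
    values,
    weights: SpatialWeights,
    variance_mode: str = "randomization",
    n_perm: int = 999,
    seed: int | None = None,
) -> Moran:
    """Functional alias for :class:`Moran`."""
    return Moran(values, weights, variance=variance_mode, n_perm=n_perm, seed=seed)


def moran_scatter(values, weights: SpatialWeights) -> tuple[np.ndarray, np.ndarray]:
    """Standardized values and their spatial lags.

    The OLS slope of lag on z equals global Moran's I when the weights are
    row-standardized (then S0 = n and the algebra collapses).
    """
    d = _deviations(values)
    z = d / d.std(ddof=0)
    return z, weights.lag(z)


def plot_moran_scatter(values, weights: SpatialWeights, ax=None):
    """Moran scatter plot (standardized value vs spatial lag) with fit line."""
    import matplotlib.pyplot as plt

    z, lag = moran_scatter(values, weights)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(z, lag, s=8, alpha=0.5)
    slope = float(np.polyfit(z, lag, 1)[0])
    xs = np.linspace(z.min(), z.max(), 2)
    ax.plot(xs, slope * xs, color="crimson", label=f"slope = {slope:.3f}")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("standardized score z")
    ax.set_ylabel("spatial lag of z")
    ax.legend()
    return ax


QUADRANTS = {(1, 1): "HH", (-1, -1): "LL", (1, -1): "HL", (-1, 1): "LH"}


class LISA:
    """Local Moran statistics with conditional-permutation significance.

    For each point i, I_i = (d_i / S^2) * sum_j w_ij d_j with S^2 the
    population variance of the scores. Significance is judged by conditional
    permutation: the value at i is held fixed while its neighbors' values
    are drawn from the remaining n-1 observations; the two-sided pseudo
    p-value is (#{|I_i*| >= |I_i|} + 1) / (n_perm + 1). Quadrants (HH, LL,
    HL, LH) come from the signs of the standardized value and its lag and
    are reported only where p_i < alpha; other points are 'ns'.

    The permutation index rows are generated once and shared across points,
    the standard strategy for vectorized conditional permutation.
    """

    def __init__(
        self,
        values,
        weights: SpatialWeights,
        n_perm: int = 999,
        alpha: float = 0.05,
        seed: int | None = None,
    ):
        d = _deviations(values)
        w = weights
        if len(d) != w.n:
            raise ValueError("values and weights size mismatch")
        n = len(d)
        s2 = (d @ d) / n
        lag_d = w.lag(d)
        self.Ii = d / s2 * lag_d
        self.lag = w.lag(np.asarray(values, float))
        z = d / d.std(ddof=0)
        self.z_value = z
        self.lag_z = w.lag(z)
        self.alpha = alpha
        self.n_perm = n_perm

        rng = np.random.default_rng(seed)
        counts = w.neighbor_counts()
        kmax = int(counts.max())
        # one (n_perm, kmax) block of positions into each point's "others" pool
        perm = np.empty((n_perm, kmax), dtype=np.int64)
        for r in range(n_perm):
            perm[r] = rng.permutation(n - 1)[:kmax]
        p_i = np.ones(n)
        for i in range(n):
            k = counts[i]
            if k == 0:
                p_i[i] = np.nan
                continue
            others = np.delete(d, i)
            draws = others[perm[:, :k]]  # (n_perm, k) neighbor deviations
            # row-standardized band weights are equal within a row: lag = mean
            lag_star = draws.mean(axis=1) if w.standardization == "row" else draws.sum(axis=1)
            ii_star = d[i] / s2 * lag_star
            p_i[i] = ((np.abs(ii_star) >= abs(self.Ii[i])).sum() + 1) / (n_perm + 1)
        self.p = p_i

        quad = np.where(
            np.isnan(p_i) | (p_i >= alpha),
            "ns",
            [
                QUADRANTS[(1 if zv > 0 else -1, 1 if lv > 0 else -1)]
                for zv, lv in zip(z, self.lag_z)
            ],
        )
        self.quadrant = quad

    def to_frame(self, point_ids=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "Ii": self.Ii,
                "z_value": self.z_value,
                "lag": self.lag,
                "p": self.p,
                "quadrant": self.quadrant,
            }
        )
        if point_ids is not None:
            out.insert(0, "point_id", np.asarray(point_ids))
        return out

    def quadrant_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.quadrant, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def local_morans_i(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LISA:
    """Functional alias for :class:`LISA`."""
    return LISA(values, weights, n_perm=n_perm, alpha=alpha, seed=seed)
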