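import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from streetstress.spatial import SpatialWeights, build_weights
from streetstress.synthetic import generate_scene_compositions, grid_points

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid100():
    """10x10 lattice of sample points at 50 m spacing."""
    return grid_points(10, 10, 50.0)


@pytest.fixture(scope="session")
def weights100(grid100):
    """Auto-threshold Manhattan band weights on the lattice (row-standardized)."""
    return build_weights(grid100, threshold="auto")


@pytest.fixture(scope="session")
def compositions100(grid100):
    return generate_scene_compositions(grid100, seed=11)


@pytest.fixture(scope="session")
def checkerboard():
    """2x2 rook-adjacent unit grid with alternating +1/-1 values.

    Perfect spatial dispersion: global Moran's I = -1 under row
    standardization, and every local statistic equals -1.
    """
    # points 0=(0,0), 1=(1,0), 2=(0,1), 3=(1,1); rook pairs share an edge
    pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)]
    rows, cols = zip(*pairs)
    w = SpatialWeights.from_arrays(rows, cols, 4, standardization="row")
    values = np.array([1.0, -1.0, -1.0, 1.0])
    return values, w


def naive_global_moran(values, dense_w):
    """Independent double-loop oracle for global Moran's I."""
    x = np.asarray(values, float)
    n = len(x)
    d = x - x.mean()
    s0 = dense_w.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += dense_w[i, j] * d[i] * d[j]
    return n * num / (s0 * (d**2).sum())


def naive_local_moran(values, dense_w):
    """Independent double-loop oracle for the local Moran statistics."""
    x = np.asarray(values, float)
    n = len(x)
    d = x - x.mean()
    s2 = (d**2).sum() / n
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += dense_w[i, j] * d[j]
        out[i] = d[i] / s2 * acc
    return out
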