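"""Shared fixtures and independent test oracles."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

SQRT2 = math.sqrt(2.0)
NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_force_min_cost(target: np.ndarray, start, end, penalty: float) -> float:
    """Exhaustive DFS over all simple 8-connected paths.

    Pruning is sound for nonnegative step costs (admissible
    remaining-distance bound plus best-known-cost-to-cell dominance), so
    the result equals the full enumeration minimum.
    """
    n_rows, n_cols = target.shape
    best = [math.inf]
    best_to = np.full((n_rows, n_cols), math.inf)
    best_to[start] = 0.0

    def dfs(r, c, cost):
        if (r, c) == tuple(end):
            best[0] = min(best[0], cost)
            return
        for dr, dc in NEIGHBORS_8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols:
                base = SQRT2 if dr and dc else 1.0
                sc = base if target[nr, nc] else base * (1.0 + penalty)
                ncost = cost + sc
                rem = max(abs(end[0] - nr), abs(end[1] - nc))
                if ncost + rem >= best[0] or ncost >= best_to[nr, nc] - 1e-12:
                    continue
                best_to[nr, nc] = ncost
                dfs(nr, nc, ncost)

    dfs(start[0], start[1], 0.0)
    return best[0]


def scipy_graph_min_cost(target: np.ndarray, start, end, penalty: float) -> float:
    """Independent route: shortest path on the explicit grid graph."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra

    n_rows, n_cols = target.shape
    n = n_rows * n_cols
    g = lil_matrix((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in NEIGHBORS_8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols:
                    base = SQRT2 if dr and dc else 1.0
                    sc = base if target[nr, nc] else base * (1.0 + penalty)
                    g[r * n_cols + c, nr * n_cols + nc] = sc
    d = dijkstra(g.tocsr(), indices=start[0] * n_cols + start[1])
    return float(d[end[0] * n_cols + end[1]])


@pytest.fixture
def one_acre_cell() -> float:
    """Cell edge length (m) giving exactly one acre per cell."""
    from rxsmoke.grid import ACRE_M2

    return math.sqrt(ACRE_M2)


@pytest.fixture
def dumbbell_landscape(one_acre_cell):
    """Two ~840-acre lobes joined by a gentle-slope neck, water all around.

    Slope is steep (35 deg) everywhere except a 4-row gentle band through
    the neck that spans the grid, so the only admissible split corridor
    runs horizontally through the neck rows.
    """
    from rxsmoke.grid import RasterGrid
    from rxsmoke.synthetic import FOREST_DECIDUOUS, WATER

    n_rows, n_cols = 40, 70
    lc = np.full((n_rows, n_cols), WATER, dtype=np.int16)
    # left lobe, right lobe, neck
    lc[5:35, 3:31] = FOREST_DECIDUOUS  # 30 x 28 = 840 cells
    lc[5:35, 39:67] = FOREST_DECIDUOUS  # 840 cells
    lc[18:22, 31:39] = FOREST_DECIDUOUS  # 4 x 8 = 32 cells
    slope = np.full((n_rows, n_cols), 35.0)
    slope[18:22, :] = 5.0  # gentle band through the neck
    return (
        RasterGrid(lc, one_acre_cell),
        RasterGrid(slope, one_acre_cell),
    )


@pytest.fixture(scope="session")
def fast_config():
    """A scaled-down end-to-end configuration for runner tests."""
    import datetime as dt

    from rxsmoke.runner import ScenarioConfig

    return ScenarioConfig(
        seed=7,
        n_rows=32,
        n_cols=32,
        conc_n_rows=40,
        conc_n_cols=40,
        met_start=dt.date(2016, 9, 1),
        met_days=100,
        favorable_target=0.25,
    )
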