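import numpy as np
import pytest

from habconn.patches import PatchGraph


@pytest.fixture
def path3_graph() -> PatchGraph:
    """Three unit-area patches in a line, consecutive gaps within dispersal
    range, total landscape area 10 km².  Hand-evaluated values:
    IIC = (17/3)/100, dIIC(middle) = 100·(17/3 − 2)/(17/3) ≈ 64.71."""
    return PatchGraph(
        node_ids=np.array([1, 2, 3]),
        node_areas=np.array([1.0, 1.0, 1.0]),
        edges={(1, 2): 0.5, (2, 3): 0.5},
        A_L=10.0,
        dispersal_distance_km=1.0,
    )


def random_patch_graph(rng: np.random.Generator, n_max: int = 40) -> PatchGraph:
    """Random graph for oracle comparisons: uniform areas, Erdős–Rényi
    edges, A_L comfortably above the habitat total."""
    n = int(rng.integers(1, n_max + 1))
    areas = rng.uniform(0.5, 20.0, size=n)
    ids = np.arange(1, n + 1)
    p_edge = rng.uniform(0.0, 0.4)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges[(int(ids[i]), int(ids[j]))] = float(rng.uniform(0.01, 1.0))
    return PatchGraph(
        node_ids=ids,
        node_areas=areas,
        edges=edges,
        A_L=float(areas.sum() * rng.uniform(1.5, 4.0)),
        dispersal_distance_km=1.0,
    )


def floyd_warshall_nl(n: int, edge_index_pairs) -> np.ndarray:
    """Link counts by an explicit O(n³) Floyd–Warshall triple loop —
    independent of the BFS used by the package."""
    nl = np.full((n, n), np.inf)
    np.fill_diagonal(nl, 0.0)
    for i, j in edge_index_pairs:
        nl[i, j] = nl[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if nl[i, k] + nl[k, j] < nl[i, j]:
                    nl[i, j] = nl[i, k] + nl[k, j]
    return nl


def brute_force_iic(areas: np.ndarray, nl: np.ndarray, A_L: float) -> float:
    """IIC by an explicit double loop over ordered pairs."""
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            if np.isfinite(nl[i, j]):
                total += areas[i] * areas[j] / (1.0 + nl[i, j])
    return total / A_L**2


def graph_edge_index_pairs(g: PatchGraph) -> list[tuple[int, int]]:
    index = {nid: k for k, nid in enumerate(g.node_ids.tolist())}
    return [(index[i], index[j]) for i, j in g.edges]
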