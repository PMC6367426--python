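"""Independent oracles used by the test suite.

These deliberately avoid the code paths (and libraries) the implementation
uses: dense Floyd–Warshall for path lengths, combinatorial path counting on
the shortest-path DAG for betweenness, and nested grid search over rotations
for superposition.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by dense Floyd–Warshall."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def average_reachability(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean finite path length and count of unreachable partners."""
    d = floyd_warshall(adj)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    reach = finite.sum(axis=1)
    L = np.full(adj.shape[0], np.nan)
    for i in range(adj.shape[0]):
        if reach[i]:
            L[i] = d[i, finite[i]].mean()
    return L, (adj.shape[0] - 1) - reach


def path_count_betweenness(adj: np.ndarray) -> np.ndarray:
    """Raw betweenness by explicit shortest-path counting on the DAG.

    For every source s: sigma(s, v) = number of shortest s→v paths, built by
    processing nodes in order of distance.  Each unordered pair (s, t)
    contributes sigma(s, v)·sigma(v, t)/sigma(s, t) to every strictly interior
    node v on a shortest path.
    """
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for v in order:
            if v == s or not np.isfinite(dist[s, v]):
                continue
            preds = [u for u in range(n) if adj[v, u] and dist[s, u] + 1 == dist[s, v]]
            sigma[s, v] = sum(sigma[s, u] for u in preds)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def random_connected_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random connected undirected graph: random spanning tree + extra edges."""
    adj = np.zeros((n, n), dtype=bool)
    nodes = rng.permutation(n)
    for k in range(1, n):
        j = nodes[k]
        i = nodes[rng.integers(0, k)]
        adj[i, j] = adj[j, i] = True
    extra = rng.random((n, n)) < 0.1
    extra = np.triu(extra, 1)
    adj |= extra | extra.T
    np.fill_diagonal(adj, False)
    return adj


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray, stages=(12.0, 1.5, 0.15, 0.015)) -> float:
    """Minimum RMSD over rotations by nested grid search (degrees per stage).

    Centroids are matched exactly (the optimal translation); rotations are
    scanned on an Euler-angle grid refined around the running best.
    """
    from scipy.spatial.transform import Rotation

    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return float(np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1))))

    best_angles, best = np.zeros(3), rmsd_of(np.zeros(3))
    span = 180.0
    for step in stages:
        grids = [np.arange(-span, span + step / 2, step) + c for c in best_angles]
        for a1 in grids[0]:
            for a2 in grids[1]:
                for a3 in grids[2]:
                    r = rmsd_of([a1, a2, a3])
                    if r < best:
                        best, best_angles = r, np.array([a1, a2, a3])
        span = step * 1.5
    return best
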