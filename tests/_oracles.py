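"""Brute-force reference implementations used only to check the package.

Everything here is written from first principles (explicit BFS, triangle
enumeration, geodesic counting) and stays independent of the code paths it
verifies.
"""

from __future__ import annotations

from collections import deque

import numpy as np

INF = float("inf")


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), INF)
    for s in range(n):
        dist[s, s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and dist[s, v] == INF:
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    return dist


def geodesic_counts(adj: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances from s and the number of shortest paths to every node."""
    n = adj.shape[0]
    dist = np.full(n, INF)
    sigma = np.zeros(n)
    dist[s] = 0
    sigma[s] = 1
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if not adj[u, v]:
                continue
            if dist[v] == INF:
                dist[v] = dist[u] + 1
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def oracle_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    coeffs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1 :]
        )
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs))


def oracle_path_length(adj: np.ndarray) -> float:
    dist = bfs_distances(adj)
    vals = [
        dist[i, j]
        for i in range(adj.shape[0])
        for j in range(adj.shape[0])
        if i != j and dist[i, j] < INF
    ]
    return float(np.mean(vals))


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    total = sum(
        1.0 / dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and dist[i, j] < INF
    )
    return total / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs.append(oracle_global_efficiency(sub))
    return float(np.mean(effs))


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Raw geodesic-fraction sums over unordered pairs (s < t)."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        _, sig = geodesic_counts(adj, s)
        sigma[s] = sig
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s, t] == INF or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def oracle_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / dist[i, j] for j in range(n) if j != i and dist[i, j] < INF
        ) / (n - 1)
    return out


def oracle_nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) >= 2:
            out[i] = oracle_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return out


def oracle_residual_partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation of x and y given columns z via residual regression."""
    z = np.column_stack([np.ones(len(x)), z])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_trapezoid(values, grid) -> float:
    total = 0.0
    for k in range(len(grid) - 1):
        total += (grid[k + 1] - grid[k]) * (values[k] + values[k + 1]) / 2.0
    return total


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj
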