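"""Degree-preserving rewiring by double-edge swaps.

A swap picks two edges (u, v) and (x, y) with four distinct endpoints and
replaces them with (u, x) and (v, y) when neither new edge exists; node
degrees are untouched.  All randomness (edge proposals, orientation flips)
is pre-drawn from a numpy Generator so results are reproducible and
independent of the execution backend; the inner rejection loop is compiled
with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _swap_loop(adj, edge_i, edge_j, prop_a, prop_b, flip, target):  # pragma: no cover
    accepted = 0
    n_prop = prop_a.shape[0]
    for t in range(n_prop):
        if accepted >= target:
            break
        a = prop_a[t]
        b = prop_b[t]
        u = edge_i[a]
        v = edge_j[a]
        x = edge_i[b]
        y = edge_j[b]
        if flip[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = 0
        adj[v, u] = 0
        adj[x, y] = 0
        adj[y, x] = 0
        adj[u, x] = 1
        adj[x, u] = 1
        adj[v, y] = 1
        adj[y, v] = 1
        if u < x:
            edge_i[a] = u
            edge_j[a] = x
        else:
            edge_i[a] = x
            edge_j[a] = u
        if v < y:
            edge_i[b] = v
            edge_j[b] = y
        else:
            edge_i[b] = y
            edge_j[b] = v
        accepted += 1
    return accepted


def double_edge_swap(
    adjacency: np.ndarray,
    rng: np.random.Generator,
    swap_factor: int = 10,
    attempt_factor: int = 100,
) -> tuple[np.ndarray, int]:
    """Return a rewired copy of ``adjacency`` and the number of accepted swaps.

    Targets ``swap_factor * |E|`` accepted swaps with at most
    ``attempt_factor * |E|`` proposals.
    """
    adj = np.ascontiguousarray(adjacency.copy().astype(np.uint8))
    ii, jj = np.nonzero(np.triu(adj, 1))
    n_edges = ii.size
    if n_edges < 2:
        return adj, 0
    target = swap_factor * n_edges
    cap = attempt_factor * n_edges
    prop_a = rng.integers(0, n_edges, size=cap)
    prop_b = rng.integers(0, n_edges, size=cap)
    flip = rng.random(cap) < 0.5
    accepted = _swap_loop(
        adj,
        ii.astype(np.int64),
        jj.astype(np.int64),
        prop_a.astype(np.int64),
        prop_b.astype(np.int64),
        flip,
        target,
    )
    return adj, int(accepted)
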