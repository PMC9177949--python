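"""Graph-theoretical network metrics on binary undirected graphs.

Global metrics: clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc, and the small-world indices
gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda, where the
random references are means over an ensemble of degree-preserving rewired
null graphs.  Nodal metrics: betweenness centrality BC, degree centrality
DC, nodal efficiency NE and nodal local efficiency NLE.  Every metric is
evaluated at each sparsity of a threshold series and summarized by the area
under its curve over the grid (composite trapezoid rule), giving one
threshold-independent value per metric (and per node for nodal metrics).

Conventions (documented in the methods note): Lp on a disconnected graph is
the mean over reachable ordered pairs, with the unreachable-pair count
reported alongside; NLE excludes the index node from its neighbor subgraph;
BC is reported unnormalized (raw geodesic-fraction sums over unordered
pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from ._rewire import double_edge_swap
from .network import BinaryGraph, ThresholdSeries

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("BC", "DC", "NE", "NLE")


class MetricError(ValueError):
    """Raised when a metric is undefined for the given graph."""


def _distances(adjacency: np.ndarray) -> np.ndarray:
    return shortest_path(adjacency, method="D", directed=False, unweighted=True)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over nodes of 2 T_i / (k_i (k_i - 1)); degree < 2 contributes 0."""
    a = g.adjacency.astype(float)
    if a.shape[0] < 3:
        raise MetricError("clustering needs at least 3 nodes")
    deg = a.sum(axis=0)
    triangles = np.diag(a @ a @ a)  # 2 * (triangles through i) * ... = path count
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, triangles / denom, 0.0)
    return float(ci.mean())


def connectivity_report(g: BinaryGraph) -> dict:
    """Number of unreachable ordered node pairs and connectedness flag."""
    d = _distances(g.adjacency)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    unreachable = int(np.isinf(d[off]).sum())
    return {"n_unreachable_pairs": unreachable, "connected": unreachable == 0}


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean geodesic length over reachable ordered pairs of distinct nodes."""
    if g.n_edges == 0:
        raise MetricError("path length is undefined for an edgeless graph")
    d = _distances(g.adjacency)
    off = ~np.eye(g.n_nodes, dtype=bool)
    vals = d[off]
    reachable = np.isfinite(vals)
    return float(vals[reachable].mean())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/d(i,j) over distinct pairs; unreachable pairs contribute 0."""
    n = g.n_nodes
    if n < 2:
        raise MetricError("efficiency needs at least 2 nodes")
    d = _distances(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _subgraph_efficiency(adjacency: np.ndarray) -> float:
    m = adjacency.shape[0]
    if m < 2:
        return 0.0
    d = shortest_path(adjacency, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def local_efficiency(g: BinaryGraph, include_node: bool = False) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    ``include_node=True`` adds the index node itself to its subgraph (a
    literal reading of "node and its adjacent neighbors"); the default
    follows the standard local-efficiency convention and excludes it.
    """
    return float(np.mean(nodal_local_efficiency(g, include_node=include_node)))


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    return g.degrees().astype(float)


def betweenness_centrality(g: BinaryGraph, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness: sum over pairs (s, t) of the fraction of s-t
    geodesics through each node (unordered pairs; raw sums by default)."""
    graph = nx.from_numpy_array(g.adjacency)
    bc = nx.betweenness_centrality(graph, normalized=normalized)
    return np.array([bc[i] for i in range(g.n_nodes)])


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """Per node: mean of 1/d(i,j) over all other nodes j."""
    n = g.n_nodes
    d = _distances(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_local_efficiency(g: BinaryGraph, include_node: bool = False) -> np.ndarray:
    """Per node: global efficiency of the subgraph induced by its neighbors
    (plus the node itself when ``include_node``); < 2 members gives 0."""
    a = g.adjacency
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = np.nonzero(a[i])[0]
        if include_node:
            nbrs = np.concatenate([nbrs, [i]])
        if nbrs.size < 2:
            continue
        out[i] = _subgraph_efficiency(a[np.ix_(nbrs, nbrs)])
    return out


@dataclass
class NodalMetricSlice:
    """All four nodal metrics of one graph, aligned to its node order."""

    bc: np.ndarray
    dc: np.ndarray
    ne: np.ndarray
    nle: np.ndarray

    def as_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {"BC": self.bc, "DC": self.dc, "NE": self.ne, "NLE": self.nle},
            index=labels,
        )


def nodal_metrics(g: BinaryGraph) -> NodalMetricSlice:
    if g.n_nodes < 3:
        raise MetricError("nodal metrics need at least 3 nodes")
    return NodalMetricSlice(
        bc=betweenness_centrality(g),
        dc=degree_centrality(g),
        ne=nodal_efficiency(g),
        nle=nodal_local_efficiency(g),
    )


# ---------------------------------------------------------------------------
# degree-preserving null models


@dataclass
class RandomReferenceStats:
    cp_rand: float
    lp_rand: float
    n_null: int
    seed: int


def random_reference_ensemble(
    g: BinaryGraph,
    n_null: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
    attempt_factor: int = 100,
) -> RandomReferenceStats:
    """Mean Cp and Lp over degree-preserving rewired null graphs.

    Each null targets ``swap_factor * |E|`` accepted double-edge swaps with
    at most ``attempt_factor * |E|`` proposals.  Graphs with no swappable
    edge pair (e.g. a star) yield identity copies with a warning.
    """
    if g.n_edges < 2:
        raise MetricError("null ensemble needs at least 2 edges")
    if n_null < 1:
        raise MetricError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    any_swapped = False
    for _ in range(n_null):
        rewired, accepted = double_edge_swap(g.adjacency, rng, swap_factor, attempt_factor)
        any_swapped |= accepted > 0
        null = BinaryGraph(rewired, g.sparsity, g.roi_labels)
        cps.append(clustering_coefficient(null))
        lps.append(characteristic_path_length(null))
    if not any_swapped:
        warnings.warn("graph could not be rewired; null ensemble is identity copies")
    return RandomReferenceStats(
        cp_rand=float(np.mean(cps)),
        lp_rand=float(np.mean(lps)),
        n_null=n_null,
        seed=seed,
    )


def small_world_indices(g: BinaryGraph, ref: RandomReferenceStats) -> tuple[float, float, float]:
    """gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    if ref.cp_rand <= 0 or ref.lp_rand <= 0:
        raise MetricError("degenerate null reference (Cp_rand or Lp_rand is 0)")
    gamma = clustering_coefficient(g) / ref.cp_rand
    lam = characteristic_path_length(g) / ref.lp_rand
    return gamma, lam, gamma / lam


# ---------------------------------------------------------------------------
# grid aggregation


def metric_auc(values, grid) -> float:
    """Composite trapezoid integral of a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape[-1] != grid.size:
        raise MetricError(
            f"value count ({values.shape[-1]}) does not match grid size ({grid.size})"
        )
    if grid.size < 2:
        raise MetricError("AUC needs at least 2 grid points")
    result = np.trapezoid(values, grid, axis=-1)
    return float(result) if np.ndim(result) == 0 else result


@dataclass
class GlobalMetricProfile:
    """Per-sparsity global metric curves plus their AUCs for one subject."""

    curves: pd.DataFrame  # index: sparsity, columns: GLOBAL_METRICS
    auc: dict[str, float]
    monotonicity: dict[str, bool]
    unreachable: pd.Series  # per-sparsity unreachable ordered-pair counts


@dataclass
class NodalMetricProfile:
    """Per-sparsity nodal metric values (sparsity x node) plus per-node AUCs."""

    curves: dict[str, pd.DataFrame]  # metric -> (sparsity x node) table
    auc: pd.DataFrame  # node x metric


def global_metrics_over_grid(
    series: ThresholdSeries,
    n_null: int = 100,
    seed: int = 0,
) -> GlobalMetricProfile:
    """All seven global metrics at every sparsity, their AUCs, and a
    monotonicity report (on a nested series Eglob never decreases and Lp
    never increases with sparsity)."""
    grid = series.grid
    rows = []
    unreachable = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(series.graphs))
    for graph, null_seed in zip(series.graphs, child_seeds):
        ref = random_reference_ensemble(graph, n_null=n_null, seed=int(null_seed) % (2**31))
        gamma, lam, sigma = small_world_indices(graph, ref)
        rows.append(
            {
                "Cp": clustering_coefficient(graph),
                "Lp": characteristic_path_length(graph),
                "Eglob": global_efficiency(graph),
                "Eloc": local_efficiency(graph),
                "gamma": gamma,
                "lambda": lam,
                "sigma": sigma,
            }
        )
        unreachable.append(connectivity_report(graph)["n_unreachable_pairs"])
    curves = pd.DataFrame(rows, index=pd.Index(grid, name="sparsity"))
    auc = {m: float(np.trapezoid(curves[m].to_numpy(), grid)) for m in GLOBAL_METRICS}
    mono = {
        "Eglob_nondecreasing": bool((np.diff(curves["Eglob"].to_numpy()) >= -1e-12).all()),
        "Lp_nonincreasing": bool((np.diff(curves["Lp"].to_numpy()) <= 1e-12).all()),
    }
    return GlobalMetricProfile(
        curves=curves,
        auc=auc,
        monotonicity=mono,
        unreachable=pd.Series(unreachable, index=curves.index, name="n_unreachable_pairs"),
    )


def nodal_metrics_over_grid(series: ThresholdSeries) -> NodalMetricProfile:
    grid = series.grid
    labels = series.graphs[0].roi_labels or list(range(series.n_nodes))
    stacks: dict[str, list[np.ndarray]] = {m: [] for m in NODAL_METRICS}
    for graph in series.graphs:
        sl = nodal_metrics(graph)
        stacks["BC"].append(sl.bc)
        stacks["DC"].append(sl.dc)
        stacks["NE"].append(sl.ne)
        stacks["NLE"].append(sl.nle)
    curves = {
        m: pd.DataFrame(np.vstack(v), index=pd.Index(grid, name="sparsity"), columns=labels)
        for m, v in stacks.items()
    }
    auc = pd.DataFrame(
        {m: np.trapezoid(curves[m].to_numpy(), grid, axis=0) for m in NODAL_METRICS},
        index=labels,
    )
    return NodalMetricProfile(curves=curves, auc=auc)
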