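"""Partial-correlation connectivity matrices and sparsity-thresholded graphs.

Each subject's N x N partial-correlation matrix (the correlation of every
region pair conditioned on the remaining N-2 regions, read off the precision
matrix) is binarized over a grid of sparsity levels: at sparsity S the
round(S * N(N-1)/2) strongest absolute partial correlations become the edges
of an undirected, loop-free graph, so every subject's graph has the same
edge count at the same sparsity.  The default grid is 0.06 to 0.40 in steps
of 0.01 (35 levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

DEFAULT_GRID = (0.06, 0.40, 0.01)


class NetworkError(ValueError):
    """Raised for invalid connectivity inputs or configuration."""


class ConditioningError(NetworkError):
    """Covariance too ill-conditioned to invert without regularization."""


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N partial-correlation matrix with zero diagonal."""

    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise NetworkError(f"connectivity matrix must be square, got {self.values.shape}")
        if len(self.roi_labels) != n:
            raise NetworkError("label count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise NetworkError("connectivity matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_labels, columns=self.roi_labels)


@dataclass
class BinaryGraph:
    """Undirected, loop-free 0/1 adjacency matrix at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise NetworkError("adjacency must be symmetric")
        if a.diagonal().any():
            raise NetworkError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise NetworkError("adjacency must be 0/1")
        self.adjacency = a.astype(np.uint8)
        if not (0.0 < self.sparsity <= 1.0):
            raise NetworkError(f"sparsity must be in (0, 1], got {self.sparsity}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edge_list(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass
class ThresholdSeries:
    """One subject's stack of binary graphs, one per sparsity level."""

    graphs: list[BinaryGraph]
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.graphs) != len(self.grid):
            raise NetworkError("one graph per grid value required")
        if len(self.grid) > 1 and not (np.diff(self.grid) > 0).all():
            raise NetworkError("sparsity grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_nodes(self) -> int:
        return self.graphs[0].n_nodes


def sparsity_grid(s_min: float = 0.06, s_max: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Arithmetic sparsity sequence, endpoint included (tolerance 1e-9)."""
    if not (0.0 < s_min <= s_max <= 1.0):
        raise NetworkError(f"need 0 < s_min <= s_max <= 1, got {s_min}, {s_max}")
    if step <= 0:
        raise NetworkError(f"step must be positive, got {step}")
    n = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    grid = s_min + step * np.arange(n)
    if grid.size == 0:
        raise NetworkError("empty sparsity grid")
    return np.round(grid, 12)


def minimum_sparsity_rule(n_nodes: int) -> float:
    """Advisory lower bound: the sparsity at which mean degree is 2 ln N.

    S (N-1) = 2 ln N  =>  S = 2 ln N / (N-1), clamped to (0, 1].  For N=90
    this gives ~0.101; the conventional grid nevertheless starts at the
    configured 0.06.
    """
    if n_nodes < 3:
        raise NetworkError("need at least 3 nodes")
    return float(min(1.0, 2.0 * np.log(n_nodes) / (n_nodes - 1)))


def _edge_count(sparsity: float, n_nodes: int) -> int:
    n_pairs = n_nodes * (n_nodes - 1) // 2
    # round half away from zero on S * n_pairs
    return int(np.floor(sparsity * n_pairs + 0.5))


def _ranked_pairs(conn: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All node pairs sorted by descending |weight|, ties in (i, j) order."""
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = np.abs(conn.values[iu, ju])
    order = np.argsort(-w, kind="stable")  # stable keeps lexicographic tie order
    if w[order].size > 1:
        ranked = w[order]
        ties_at_cut = np.unique(ranked).size < ranked.size
        if ties_at_cut:
            warnings.warn(
                "tied absolute partial correlations; breaking ties in (i, j) order",
                stacklevel=3,
            )
    return iu[order], ju[order], w[order]


def partial_correlation_matrix(
    ts,
    shrinkage: float = 0.0,
    rank_policy: str = "error",
) -> ConnectivityMatrix:
    """Partial correlations of all region pairs conditioned on the rest.

    Computed as -P_ij / sqrt(P_ii P_jj) from the precision matrix
    P = S^-1 of the sample covariance S.  ``shrinkage`` applies diagonal
    loading S <- (1-lam) S + lam * mean(diag(S)) I before inversion.

    ``rank_policy`` controls behaviour when S is singular or the series is
    too short (T <= N):

    - ``"error"`` (default): raise :class:`ConditioningError` suggesting
      shrinkage;
    - ``"pseudoinverse"``: compute the Moore-Penrose precision, i.e. the
      partial-correlation structure restricted to the span of the data.
      This is the appropriate choice after nuisance regression, which makes
      the columns exactly collinear (diagonal loading would let the null
      direction dominate the loaded precision).
    """
    from .preprocess import ROITimeSeries  # avoid cycle at import time

    if not isinstance(ts, ROITimeSeries):
        ts = ROITimeSeries(ts)
    x = ts.to_numpy()
    t, n = x.shape
    variances = x.var(axis=0)
    if (variances <= 0).any():
        bad = [ts.roi_labels[i] for i in np.nonzero(variances <= 0)[0]]
        raise NetworkError(f"zero-variance ROI columns: {bad}")
    if t <= n and shrinkage == 0.0 and rank_policy == "error":
        raise ConditioningError(
            f"T={t} <= N={n}: sample covariance is singular; enable shrinkage "
            "or rank_policy='pseudoinverse'"
        )
    s = np.cov(x, rowvar=False)
    if shrinkage > 0.0:
        mu = float(np.trace(s)) / n
        s = (1.0 - shrinkage) * s + shrinkage * mu * np.eye(n)
    if rank_policy == "pseudoinverse":
        precision = np.linalg.pinv(s, rcond=1e-8, hermitian=True)
    elif rank_policy == "error":
        cond = np.linalg.cond(s)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConditioningError(
                f"sample covariance is ill-conditioned (cond={cond:.3g}); "
                "enable shrinkage or rank_policy='pseudoinverse'"
            )
        precision = np.linalg.inv(s)
    else:
        raise NetworkError(f"unknown rank_policy {rank_policy!r}")
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 0.0)
    return ConnectivityMatrix(pc, ts.roi_labels)


def binarize_at_sparsity(conn: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Keep the round(S * N(N-1)/2) strongest |partial correlations| as edges."""
    if not (0.0 < s <= 1.0):
        raise NetworkError(f"sparsity must be in (0, 1], got {s}")
    if not np.abs(conn.values).any():
        raise NetworkError("all-zero connectivity matrix cannot be thresholded")
    n = conn.n_nodes
    k = _edge_count(s, n)
    ii, jj, _ = _ranked_pairs(conn)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:k], jj[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adj, s, conn.roi_labels)


def build_threshold_series(conn: ConnectivityMatrix, grid=None) -> ThresholdSeries:
    """One binary graph per grid sparsity; edge sets are nested along the grid."""
    if grid is None:
        grid = sparsity_grid(*DEFAULT_GRID)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise NetworkError("empty sparsity grid")
    if not np.abs(conn.values).any():
        raise NetworkError("all-zero connectivity matrix cannot be thresholded")
    n = conn.n_nodes
    ii, jj, _ = _ranked_pairs(conn)
    graphs = []
    for s in grid:
        k = _edge_count(float(s), n)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[ii[:k], jj[:k]] = 1
        adj |= adj.T
        graphs.append(BinaryGraph(adj, float(s), conn.roi_labels))
    return ThresholdSeries(graphs, grid)


# ---------------------------------------------------------------------------
# serialization


def connectivity_to_tsv(conn: ConnectivityMatrix, path) -> None:
    conn.to_frame().to_csv(path, sep="\t")


def connectivity_from_tsv(path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(frame.to_numpy(), list(frame.columns))


def write_brainnet_edge(graph: BinaryGraph, path) -> None:
    """BrainNet Viewer ``.edge`` file: whitespace-separated N x N 0/1 matrix."""
    np.savetxt(path, graph.adjacency, fmt="%d", delimiter="\t")


def write_brainnet_node(
    labels: list[str],
    path,
    colors: dict[str, int] | None = None,
    sizes: dict[str, float] | None = None,
    centroids: pd.DataFrame | None = None,
) -> None:
    """BrainNet Viewer ``.node`` file: x, y, z, color, size, label per row.

    Coordinates come from the packaged synthetic centroid table unless a
    ``roi_label,x,y,z`` frame is supplied.
    """
    from .atlas import load_centroids

    table = centroids if centroids is not None else load_centroids()
    lookup = table.set_index("roi_label")
    with open(path, "w") as fh:
        for label in labels:
            if label in lookup.index:
                x, y, z = lookup.loc[label, ["x", "y", "z"]]
            else:
                x = y = z = 0.0
            color = (colors or {}).get(label, 1)
            size = (sizes or {}).get(label, 1.0)
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{color}\t{size:.3f}\t{label}\n")
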