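"""Rich-club organization: hub selection and edge-class decomposition.

Rich-club nodes are the top 12% of regions (10 of 90) by nodal degree
averaged over the group's subjects and the full sparsity grid.  Edges then
fall into three classes that partition the edge set: rich-club connections
join two rich nodes, feeder connections join a rich and a non-rich node,
and local connections join two non-rich nodes.  Selection is performed per
group because hub membership itself reorganizes between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .network import BinaryGraph, ThresholdSeries

EDGE_CLASSES = ("rich", "feeder", "local")
DEFAULT_RICH_FRACTION = 0.12


class RichClubError(ValueError):
    """Raised for invalid rich-club inputs."""


def group_average_degree(series_list: list[ThresholdSeries]) -> pd.Series:
    """Per-node degree averaged over subjects and sparsity levels."""
    if not series_list:
        raise RichClubError("need at least one subject")
    first = series_list[0]
    labels = first.graphs[0].roi_labels or list(range(first.n_nodes))
    grid0 = first.grid
    total = np.zeros(first.n_nodes)
    for series in series_list:
        lbl = series.graphs[0].roi_labels or list(range(series.n_nodes))
        if lbl != labels or not np.array_equal(series.grid, grid0):
            raise RichClubError("subjects must share node labels and sparsity grid")
        total += np.mean([g.degrees() for g in series.graphs], axis=0)
    return pd.Series(total / len(series_list), index=labels, name="avg_degree")


def select_rich_nodes(avg_degree: pd.Series, fraction: float = DEFAULT_RICH_FRACTION) -> list:
    """Top floor(fraction * N) nodes by average degree.

    Ties spanning the cutoff are broken by node order (a warning is
    emitted) so selection is deterministic.
    """
    if not (0.0 < fraction < 1.0):
        raise RichClubError(f"fraction must be in (0, 1), got {fraction}")
    n = len(avg_degree)
    k = int(np.floor(fraction * n))
    values = avg_degree.to_numpy(dtype=float)
    order = np.argsort(-values, kind="stable")  # stable = index-order tie break
    if k < n and values[order[k - 1]] == values[order[k]]:
        warnings.warn("tie at the rich-club cutoff; resolved in node order")
    return [avg_degree.index[i] for i in order[:k]]


def classify_edges(g: BinaryGraph, rich: set) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every edge rich/feeder/local; counts partition the edge set."""
    labels = g.roi_labels or list(range(g.n_nodes))
    unknown = set(rich) - set(labels)
    if unknown:
        raise RichClubError(f"rich nodes not in graph: {sorted(map(str, unknown))}")
    is_rich = np.array([lbl in rich for lbl in labels])
    edges = g.edge_list()
    n_rich_ends = is_rich[edges[:, 0]].astype(int) + is_rich[edges[:, 1]].astype(int)
    classes = np.array(["local", "feeder", "rich"])[n_rich_ends]
    table = pd.DataFrame(
        {
            "node_i": [labels[i] for i in edges[:, 0]],
            "node_j": [labels[j] for j in edges[:, 1]],
            "edge_class": classes,
        }
    )
    counts = {c: int((classes == c).sum()) for c in EDGE_CLASSES}
    assert sum(counts.values()) == g.n_edges
    return table, counts


def class_strengths(series_list: list[ThresholdSeries], rich: set) -> pd.DataFrame:
    """Per-subject mean edge counts per class, averaged over the grid.

    One row per subject with columns rich/feeder/local; the row sum equals
    the subject's mean edge count over sparsity levels.
    """
    rows = []
    for series in series_list:
        acc = dict.fromkeys(EDGE_CLASSES, 0.0)
        for graph in series.graphs:
            _, counts = classify_edges(graph, rich)
            for c in EDGE_CLASSES:
                acc[c] += counts[c]
        rows.append({c: acc[c] / len(series.graphs) for c in EDGE_CLASSES})
    return pd.DataFrame(rows)


@dataclass
class RichClubResult:
    """Group-level rich-club summary."""

    rich_nodes: list
    avg_degree: pd.Series
    strengths: pd.DataFrame  # per subject x class

    def membership_table(self, group: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": group,
                "rank": np.arange(1, len(self.rich_nodes) + 1),
                "roi_label": self.rich_nodes,
                "avg_degree": [self.avg_degree[r] for r in self.rich_nodes],
            }
        )


def export_brainnet(g: BinaryGraph, rich: set, path_prefix) -> None:
    """Write BrainNet Viewer ``.node``/``.edge`` files color-coded by class.

    Rich nodes get color 2 and double size; the companion edge file is the
    graph's adjacency matrix.
    """
    from .network import write_brainnet_edge, write_brainnet_node

    labels = g.roi_labels or [str(i) for i in range(g.n_nodes)]
    colors = {lbl: (2 if lbl in rich else 1) for lbl in labels}
    sizes = {lbl: (2.0 if lbl in rich else 1.0) for lbl in labels}
    write_brainnet_node(labels, f"{path_prefix}.node", colors=colors, sizes=sizes)
    write_brainnet_edge(g, f"{path_prefix}.edge")


def rich_club_analysis(
    series_list: list[ThresholdSeries], fraction: float = DEFAULT_RICH_FRACTION
) -> RichClubResult:
    """Select rich nodes from the group-average degree and decompose edges."""
    avg = group_average_degree(series_list)
    rich = select_rich_nodes(avg, fraction)
    strengths = class_strengths(series_list, set(rich))
    return RichClubResult(rich_nodes=rich, avg_degree=avg, strengths=strengths)
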