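"""Intra- and inter-modular connection strengths over a fixed atlas partition.

The partition is anatomical (the six AAL90 lobe modules by default), not
data driven.  For each binarized graph, an edge is intra-modular when both
endpoints share a module and inter-modular otherwise; a subject's mean
strength of a module is the average count of its intra-modular (resp.
inter-modular) connections over the sparsity grid.  Per-pair densities
(counts normalized by the number of available node pairs) are reported
alongside because raw counts scale with module size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ThresholdSeries


class AtlasError(ValueError):
    """Raised for invalid atlas/partition tables."""


@dataclass
class ModulePartition:
    """Assignment of every ROI label to exactly one module."""

    assignment: dict[str, str]
    module_names: list[str]

    def __post_init__(self) -> None:
        missing = set(self.assignment.values()) - set(self.module_names)
        if missing:
            raise AtlasError(f"modules {sorted(missing)} not in module_names")

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def labels(self) -> list[str]:
        return list(self.assignment)

    def indices(self, roi_labels: list[str]) -> np.ndarray:
        """Module index of each ROI in ``roi_labels`` order."""
        lookup = {m: k for k, m in enumerate(self.module_names)}
        try:
            return np.array([lookup[self.assignment[r]] for r in roi_labels])
        except KeyError as exc:
            raise AtlasError(f"ROI {exc.args[0]!r} has no module assignment") from exc


def module_partition(atlas_table: pd.DataFrame) -> ModulePartition:
    """Build a partition from a ``roi_label,module`` table."""
    if not {"roi_label", "module"} <= set(atlas_table.columns):
        raise AtlasError("atlas table needs 'roi_label' and 'module' columns")
    if atlas_table["roi_label"].duplicated().any():
        dupes = atlas_table.loc[atlas_table["roi_label"].duplicated(), "roi_label"].tolist()
        raise AtlasError(f"duplicate ROI rows: {dupes}")
    if atlas_table[["roi_label", "module"]].isna().any().any():
        raise AtlasError("atlas table contains unassigned entries")
    names = list(dict.fromkeys(atlas_table["module"]))  # first-appearance order
    assignment = dict(zip(atlas_table["roi_label"], atlas_table["module"]))
    return ModulePartition(assignment=assignment, module_names=names)


def default_partition() -> ModulePartition:
    from .atlas import load_module_table

    return module_partition(load_module_table())


@dataclass
class ModularConnectivity:
    """Mean modular connection strengths of one subject over the grid."""

    intra_strength: pd.Series  # per module: mean intra edge count
    inter_strength: pd.Series  # per module: mean edge count to all other modules
    pair_counts: pd.DataFrame  # module x module mean counts (diag = intra)
    intra_density: pd.Series
    inter_density: pd.Series


def modular_connection_strengths(
    series: ThresholdSeries, partition: ModulePartition
) -> ModularConnectivity:
    """Count intra- and inter-modular edges at each sparsity, then average.

    At every sparsity the intra counts plus the unordered inter-pair counts
    sum to the graph's edge count (conservation).
    """
    labels = series.graphs[0].roi_labels
    if labels is None:
        raise AtlasError("threshold series has no ROI labels to align with the partition")
    if set(labels) - set(partition.labels()):
        unknown = sorted(set(labels) - set(partition.labels()))
        raise AtlasError(f"graph labels missing from partition: {unknown}")
    mod_idx = partition.indices(labels)
    k = partition.n_modules
    sizes = np.bincount(mod_idx, minlength=k).astype(float)

    totals = np.zeros((k, k))
    for graph in series.graphs:
        edges = graph.edge_list()
        mi = mod_idx[edges[:, 0]]
        mj = mod_idx[edges[:, 1]]
        counts = np.zeros((k, k))
        np.add.at(counts, (np.minimum(mi, mj), np.maximum(mi, mj)), 1)
        assert counts.sum() == graph.n_edges  # conservation at every sparsity
        totals += counts
    mean_counts = totals / len(series.graphs)
    sym = mean_counts + mean_counts.T - np.diag(np.diag(mean_counts))

    intra = np.diag(sym).copy()
    inter = sym.sum(axis=1) - intra
    intra_pairs = sizes * (sizes - 1) / 2
    inter_pairs = sizes * (sizes.sum() - sizes)
    with np.errstate(invalid="ignore", divide="ignore"):
        intra_density = np.where(intra_pairs > 0, intra / intra_pairs, 0.0)
        inter_density = np.where(inter_pairs > 0, inter / inter_pairs, 0.0)

    names = partition.module_names
    return ModularConnectivity(
        intra_strength=pd.Series(intra, index=names, name="intra_strength"),
        inter_strength=pd.Series(inter, index=names, name="inter_strength"),
        pair_counts=pd.DataFrame(sym, index=names, columns=names),
        intra_density=pd.Series(intra_density, index=names, name="intra_density"),
        inter_density=pd.Series(inter_density, index=names, name="inter_density"),
    )
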