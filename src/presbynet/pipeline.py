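"""End-to-end orchestration: cohort -> preprocessing -> networks -> metrics
-> modularity -> rich club -> group statistics.

A single :class:`PipelineConfig` (fully serializable, seed included) drives
the whole run; identical config and seed reproduce identical tables.  Each
stage failure is re-raised with the stage name and subject id attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import (
    GLOBAL_METRICS,
    NODAL_METRICS,
    global_metrics_over_grid,
    nodal_metrics_over_grid,
)
from .modularity import ModulePartition, default_partition, modular_connection_strengths
from .network import (
    DEFAULT_GRID,
    build_threshold_series,
    partial_correlation_matrix,
    sparsity_grid,
)
from .preprocess import MotionTrace, ROITimeSeries, preprocess_subject
from .richclub import DEFAULT_RICH_FRACTION, rich_club_analysis
from .stats import compare_metric_groups
from .synthetic import CohortConfig, generate_cohort


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage and subject."""


@dataclass
class PipelineConfig:
    """Parameters of a full run (defaults follow the study conventions)."""

    cohort: CohortConfig | None = None
    data_dir: str | None = None
    n_discard: int = 10
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    bandpass_hz: tuple[float, float] | None = (0.01, 0.08)
    grid: tuple[float, float, float] = DEFAULT_GRID
    shrinkage: float = 0.0
    rank_policy: str = "pseudoinverse"
    n_null: int = 100
    rich_fraction: float = DEFAULT_RICH_FRACTION
    alpha: float = 0.05
    compute_nodal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort is None and self.data_dir is None:
            raise PipelineError("config needs either a synthetic cohort or a data directory")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "data_dir": self.data_dir,
            "n_discard": self.n_discard,
            "trans_limit_mm": self.trans_limit_mm,
            "rot_limit_deg": self.rot_limit_deg,
            "bandpass_hz": list(self.bandpass_hz) if self.bandpass_hz else None,
            "grid": list(self.grid),
            "shrinkage": self.shrinkage,
            "rank_policy": self.rank_policy,
            "n_null": self.n_null,
            "rich_fraction": self.rich_fraction,
            "alpha": self.alpha,
            "compute_nodal": self.compute_nodal,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if data.get("cohort"):
            data["cohort"] = CohortConfig(**data["cohort"])
        if data.get("bandpass_hz"):
            data["bandpass_hz"] = tuple(data["bandpass_hz"])
        if data.get("grid"):
            data["grid"] = tuple(data["grid"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Everything a run produced, regenerable from config + seed."""

    config: PipelineConfig
    roster: pd.DataFrame
    inclusion: pd.DataFrame
    global_auc: pd.DataFrame  # subject x metric
    global_curves: pd.DataFrame  # tidy: subject_id, sparsity, metric, value
    nodal_auc: pd.DataFrame | None  # tidy: subject_id, node, metric, auc
    modular: pd.DataFrame  # tidy per subject x module
    rich_membership: pd.DataFrame  # group, rank, roi_label, avg_degree
    rich_strengths: pd.DataFrame  # subject_id, rich, feeder, local
    global_stats: "pd.DataFrame"
    global_posthoc: pd.DataFrame
    nodal_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    version: str = __version__


def read_timeseries(path, tr_s: float = 2.0, expected_labels: list[str] | None = None) -> ROITimeSeries:
    """Read a TSV time-series table (rows = time points, columns = ROIs).

    When ``expected_labels`` is given, the file must contain exactly those
    columns; a permuted header is realigned by label with a warning.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.isna().any().any():
        bad = np.argwhere(frame.isna().to_numpy())[0]
        raise PipelineError(
            f"{path}: non-numeric or missing cell at row {bad[0]}, column {frame.columns[bad[1]]!r}"
        )
    if expected_labels is not None:
        if set(frame.columns) != set(expected_labels):
            raise PipelineError(
                f"{path}: columns do not match the atlas "
                f"({len(frame.columns)} columns vs {len(expected_labels)} expected)"
            )
        if list(frame.columns) != list(expected_labels):
            warnings.warn(f"{path}: column order permuted; realigning by label")
            frame = frame[expected_labels]
    return ROITimeSeries(frame, tr_s)


def _load_data_dir(directory, tr_s: float, expected_labels: list[str] | None):
    directory = Path(directory)
    roster = pd.read_csv(directory / "roster.csv")
    timeseries, motion = {}, {}
    for sid in roster["subject_id"]:
        timeseries[sid] = read_timeseries(
            directory / f"{sid}_timeseries.tsv", tr_s, expected_labels
        )
        motion[sid] = MotionTrace(
            pd.read_csv(directory / f"{sid}_motion.tsv", sep="\t", float_precision="round_trip")
        )
    return roster, timeseries, motion


def run_pipeline(config: PipelineConfig, partition: ModulePartition | None = None) -> RunReport:
    partition = partition or default_partition()
    grid = sparsity_grid(*config.grid)

    # --- stage: data ---
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
        roster, timeseries, motion = cohort.roster, cohort.timeseries, cohort.motion
        tr_s = config.cohort.tr_s
    else:
        tr_s = 2.0
        roster, timeseries, motion = _load_data_dir(
            config.data_dir, tr_s, partition.labels()
        )

    # --- stage: preprocessing ---
    cleaned: dict[str, ROITimeSeries] = {}
    inclusion_rows = []
    for sid in roster["subject_id"]:
        try:
            ts, log = preprocess_subject(
                timeseries[sid],
                motion[sid],
                n_discard=config.n_discard,
                trans_limit_mm=config.trans_limit_mm,
                rot_limit_deg=config.rot_limit_deg,
                bandpass_hz=config.bandpass_hz,
            )
        except Exception as exc:
            raise PipelineError(f"stage=preprocess subject={sid}: {exc}") from exc
        row = {"subject_id": sid, "included": ts is not None}
        row.update(log.motion.as_dict() if log.motion else {})
        inclusion_rows.append(row)
        if ts is not None:
            cleaned[sid] = ts
    inclusion = pd.DataFrame(inclusion_rows)
    if not cleaned:
        raise PipelineError("stage=preprocess: every subject was excluded; empty cohort")
    roster = roster[roster["subject_id"].isin(cleaned)].reset_index(drop=True)

    # --- stage: network construction ---
    series_by_subject = {}
    for sid, ts in cleaned.items():
        try:
            conn = partial_correlation_matrix(
                ts, shrinkage=config.shrinkage, rank_policy=config.rank_policy
            )
            series_by_subject[sid] = build_threshold_series(conn, grid)
        except Exception as exc:
            raise PipelineError(f"stage=network subject={sid}: {exc}") from exc

    # --- stage: graph metrics ---
    null_seeds = np.random.SeedSequence(config.seed).generate_state(len(series_by_subject))
    auc_rows, curve_rows, nodal_rows = [], [], []
    for (sid, series), null_seed in zip(series_by_subject.items(), null_seeds):
        try:
            profile = global_metrics_over_grid(
                series, n_null=config.n_null, seed=int(null_seed) % (2**31)
            )
        except Exception as exc:
            raise PipelineError(f"stage=metrics subject={sid}: {exc}") from exc
        auc_rows.append({"subject_id": sid, **profile.auc})
        tidy = profile.curves.reset_index().melt(
            id_vars="sparsity", var_name="metric", value_name="value"
        )
        tidy.insert(0, "subject_id", sid)
        curve_rows.append(tidy)
        if config.compute_nodal:
            nodal = nodal_metrics_over_grid(series)
            frame = nodal.auc.reset_index(names="node").melt(
                id_vars="node", var_name="metric", value_name="auc"
            )
            frame.insert(0, "subject_id", sid)
            nodal_rows.append(frame)
    global_auc = pd.DataFrame(auc_rows)
    global_curves = pd.concat(curve_rows, ignore_index=True)
    nodal_auc = pd.concat(nodal_rows, ignore_index=True) if nodal_rows else None

    # --- stage: modularity ---
    modular_rows = []
    for sid, series in series_by_subject.items():
        try:
            mc = modular_connection_strengths(series, partition)
        except Exception as exc:
            raise PipelineError(f"stage=modularity subject={sid}: {exc}") from exc
        for module in partition.module_names:
            modular_rows.append(
                {
                    "subject_id": sid,
                    "module": module,
                    "intra_strength": mc.intra_strength[module],
                    "inter_strength": mc.inter_strength[module],
                    "intra_density": mc.intra_density[module],
                    "inter_density": mc.inter_density[module],
                }
            )
    modular = pd.DataFrame(modular_rows)

    # --- stage: rich club (per group) ---
    membership_rows, strength_rows = [], []
    for group, sub in roster.groupby("group", sort=False):
        sids = sub["subject_id"].tolist()
        try:
            result = rich_club_analysis(
                [series_by_subject[s] for s in sids], fraction=config.rich_fraction
            )
        except Exception as exc:
            raise PipelineError(f"stage=richclub group={group}: {exc}") from exc
        membership_rows.append(result.membership_table(group))
        strengths = result.strengths.copy()
        strengths.insert(0, "subject_id", sids)
        strength_rows.append(strengths)
    rich_membership = pd.concat(membership_rows, ignore_index=True)
    rich_strengths = pd.concat(strength_rows, ignore_index=True)

    # --- stage: statistics ---
    try:
        global_report = compare_metric_groups(
            global_auc, roster, list(GLOBAL_METRICS), alpha=config.alpha,
            bonferroni_m=1,
        )
        nodal_stats = {}
        if nodal_auc is not None:
            n_nodes = nodal_auc["node"].nunique()
            for metric in NODAL_METRICS:
                wide = (
                    nodal_auc[nodal_auc["metric"] == metric]
                    .pivot(index="subject_id", columns="node", values="auc")
                    .reset_index()
                )
                nodal_stats[metric] = compare_metric_groups(
                    wide,
                    roster,
                    [c for c in wide.columns if c != "subject_id"],
                    alpha=config.alpha,
                    bonferroni_m=n_nodes,
                ).posthoc
    except Exception as exc:
        raise PipelineError(f"stage=stats: {exc}") from exc

    return RunReport(
        config=config,
        roster=roster,
        inclusion=inclusion,
        global_auc=global_auc,
        global_curves=global_curves,
        nodal_auc=nodal_auc,
        modular=modular,
        rich_membership=rich_membership,
        rich_strengths=rich_strengths,
        global_stats=global_report.rows,
        global_posthoc=global_report.posthoc,
        nodal_stats=nodal_stats,
    )


def write_report(report: RunReport, directory) -> list[str]:
    """Write all report tables (CSV) plus a JSON provenance record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(directory / name, index=False)
        written.append(name)

    _csv(report.roster, "roster.csv")
    _csv(report.inclusion, "inclusion.csv")
    _csv(report.global_auc, "global_auc.csv")
    _csv(report.global_curves, "global_curves.csv")
    if report.nodal_auc is not None:
        _csv(report.nodal_auc, "nodal_auc.csv")
    _csv(report.modular, "modular_strengths.csv")
    _csv(report.rich_membership, "richclub_membership.csv")
    _csv(report.rich_strengths, "richclub_strengths.csv")
    _csv(report.global_stats, "global_stats.csv")
    _csv(report.global_posthoc, "global_posthoc.csv")
    for metric, frame in report.nodal_stats.items():
        _csv(frame, f"nodal_stats_{metric}.csv")
    provenance = {
        "version": report.version,
        "config": report.config.to_dict(),
        "n_subjects": int(len(report.roster)),
        "tables": written,
    }
    with open(directory / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    written.append("run.json")
    return written
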