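"""Synthetic cohorts with planted modular small-world covariance structure.

Two ground-truth constructions are provided, both over the AAL90 six-module
partition:

``plant_covariance`` (block design)
    A block-constant correlation matrix: ``within_module_corr`` inside each
    module, ``between_module_corr`` elsewhere, optionally enriched hubs via
    cross-module factor loadings.  This is the structure used for the
    small-world and grid-trend analyses: the within-module blocks survive
    partial-correlation estimation as dense positive within-module partial
    correlations, giving binarized graphs high clustering relative to
    degree-preserving null graphs.

``plant_ggm_covariance`` (modular small-world graphical model)
    The planted structure is specified directly in partial-correlation
    space, because that is the quantity the analysis pipeline estimates: a
    ring lattice of within-module links (clustering), star links from hub
    regions to cross-module partners plus a hub-hub ring (integration and a
    planted rich club), and a global shared component mixed into the
    covariance (removed downstream by global-mean regression).  Group
    effects scale the within-lattice strength (segregation) and the
    hub-link strength (integration): the patient presets increase
    segregation and weaken hubs, reproducing the reported effect
    directions (Cp and Lp up, Eglob down).

Demographics are sampled truncated-normal at the published group means/SDs
with MoCA and PTA truncated at their diagnostic boundaries, so the clinical
grouping rules reproduce the configured group sizes exactly; sex is
assigned to exactly match the configured male/female counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
import yaml

from .preprocess import MOTION_COLUMNS, MotionTrace, ROITimeSeries

DEFAULT_GROUP_SIZES = {"PCD": 30, "PNCD": 30, "HC": 50}
DEFAULT_N_TIMEPOINTS = 230
DEFAULT_TR_S = 2.0

#: top-degree regions of the healthy-control group-average network, used as
#: the default planted hub set
DEFAULT_HUB_LABELS = (
    "Supp_Motor_Area_L",
    "Supp_Motor_Area_R",
    "Precuneus_L",
    "Precuneus_R",
    "Paracentral_Lobule_L",
    "Paracentral_Lobule_R",
    "Temporal_Mid_L",
    "Temporal_Mid_R",
    "Temporal_Sup_R",
    "Occipital_Mid_L",
)

#: published group means/SDs (age years, education years, PTA dB HL, MoCA)
DEFAULT_DEMOGRAPHICS = {
    "PCD": {
        "age": (63.03, 7.30),
        "education_years": (10.40, 2.18),
        "pta_left": (33.08, 3.79),
        "pta_right": (33.16, 6.66),
        "moca": (24.57, 0.77),
        "n_male": 14,
        "n_total": 30,
    },
    "PNCD": {
        "age": (62.47, 7.12),
        "education_years": (11.47, 1.72),
        "pta_left": (33.11, 5.00),
        "pta_right": (33.52, 5.28),
        "moca": (26.63, 0.72),
        "n_male": 12,
        "n_total": 30,
    },
    "HC": {
        "age": (61.08, 3.93),
        "education_years": (10.78, 1.79),
        "pta_left": (17.93, 5.84),
        "pta_right": (17.40, 5.19),
        "moca": (26.74, 1.23),
        "n_male": 24,
        "n_total": 50,
    },
}

#: group-effect preset reproducing the reported patient effect directions
PRESBYCUSIS_GROUP_EFFECT = {
    "PCD": {"within_scale": 2.2, "hub_scale": 0.2},
    "PNCD": {"within_scale": 1.6, "hub_scale": 0.6},
    "HC": {"within_scale": 1.0, "hub_scale": 1.0},
}


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


class DefinitenessError(ValueError):
    """Raised when a covariance specification is not positive definite."""


def _default_partition_map() -> dict[str, str]:
    from .atlas import load_module_table

    table = load_module_table()
    return dict(zip(table["roi_label"], table["module"]))


def _module_indices(partition: dict[str, str]) -> tuple[list[str], np.ndarray, list[str]]:
    labels = list(partition)
    module_names = list(dict.fromkeys(partition.values()))
    lookup = {m: k for k, m in enumerate(module_names)}
    idx = np.array([lookup[partition[r]] for r in labels])
    return labels, idx, module_names


# ---------------------------------------------------------------------------
# block-constant design


@dataclass
class CovarianceSpec:
    """Block-constant correlation structure with optional hub enrichment.

    ``hub_strength`` is the cross-module factor loading of each hub node;
    hubs gain elevated correlations with every other module, hence larger
    covariance row sums, while positive definiteness is guaranteed by the
    factor construction (validated by an explicit eigenvalue check).
    """

    partition: dict[str, str] = field(default_factory=_default_partition_map)
    within_module_corr: float = 0.5
    between_module_corr: float = 0.1
    hub_nodes: tuple[str, ...] = ()
    hub_strength: float = 0.2
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ConfigError(f"within_module_corr must be in [0, 1), got {self.within_module_corr}")
        if not (0.0 <= self.between_module_corr < 1.0):
            raise ConfigError(
                f"between_module_corr must be in [0, 1), got {self.between_module_corr}"
            )
        if self.within_module_corr < self.between_module_corr:
            raise ConfigError("within_module_corr must be >= between_module_corr")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        unknown = set(self.hub_nodes) - set(self.partition)
        if unknown:
            raise ConfigError(f"hub nodes not in partition: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.partition)


def plant_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Build the covariance implied by a :class:`CovarianceSpec`.

    Constructed from a latent factor model (one global factor carrying the
    between-module correlation, one factor per module carrying the
    within-module excess, cross-module loadings for hubs), so the no-hub
    case is exactly block-constant and the result is positive
    semi-definite by construction; an eigenvalue check still guards the
    unique-variance constraint.
    """
    labels, mod_idx, module_names = _module_indices(spec.partition)
    n = len(labels)
    m = len(module_names)
    b = spec.between_module_corr
    a = spec.within_module_corr - b
    loadings = np.zeros((n, 1 + m))
    loadings[:, 0] = np.sqrt(b)
    loadings[np.arange(n), 1 + mod_idx] = np.sqrt(a)
    hub_pos = {labels.index(h) for h in spec.hub_nodes}
    for h in hub_pos:
        for k in range(m):
            if k != mod_idx[h]:
                loadings[h, 1 + k] = spec.hub_strength
    unique = 1.0 - (loadings**2).sum(axis=1)
    cov = loadings @ loadings.T + np.diag(unique)
    smallest = float(np.linalg.eigvalsh(cov).min())
    if unique.min() <= 0 or smallest <= 0:
        raise DefinitenessError(
            f"covariance specification is not positive definite "
            f"(smallest eigenvalue {min(smallest, float(unique.min())):.6g}); "
            "reduce hub_strength or the correlations"
        )
    return cov * spec.noise_sd**2


# ---------------------------------------------------------------------------
# modular small-world graphical-model design


@dataclass
class GGMCohortSpec:
    """Planted partial-correlation structure for cohort simulation.

    Within-module ring lattices (each node linked to its ``lattice_degree``
    nearest module neighbors at partial correlation ``within_partial``),
    hub stars (``hub_partners`` cross-module links plus a ``hub_ring`` of
    hub-hub links at ``hub_partial``; hubs carry no within-module links),
    and a ``global_corr`` shared component mixed into the covariance.
    ``within_scale`` and ``hub_scale`` are the group-effect dials.
    """

    partition: dict[str, str] = field(default_factory=_default_partition_map)
    lattice_degree: int = 4
    within_partial: float = 0.10
    hub_nodes: tuple[str, ...] = DEFAULT_HUB_LABELS
    hub_partial: float = 0.12
    hub_partners: int = 10
    hub_ring: int = 4
    global_corr: float = 0.1
    noise_sd: float = 1.0
    within_scale: float = 1.0
    hub_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lattice_degree < 2 or self.lattice_degree % 2:
            raise ConfigError("lattice_degree must be an even count >= 2")
        if not (0.0 <= self.global_corr < 1.0):
            raise ConfigError("global_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        unknown = set(self.hub_nodes) - set(self.partition)
        if unknown:
            raise ConfigError(f"hub nodes not in partition: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.partition)

    def with_effect(self, within_scale: float, hub_scale: float) -> "GGMCohortSpec":
        return GGMCohortSpec(
            partition=self.partition,
            lattice_degree=self.lattice_degree,
            within_partial=self.within_partial,
            hub_nodes=self.hub_nodes,
            hub_partial=self.hub_partial,
            hub_partners=self.hub_partners,
            hub_ring=self.hub_ring,
            global_corr=self.global_corr,
            noise_sd=self.noise_sd,
            within_scale=within_scale,
            hub_scale=hub_scale,
        )


def planted_partial_matrix(spec: GGMCohortSpec) -> np.ndarray:
    """The target partial-correlation pattern (zero diagonal)."""
    labels, mod_idx, module_names = _module_indices(spec.partition)
    n = len(labels)
    p = np.zeros((n, n))
    pw = spec.within_partial * spec.within_scale
    hub_pos = [labels.index(h) for h in spec.hub_nodes]
    hub_set = set(hub_pos)
    for k in range(len(module_names)):
        members = np.nonzero(mod_idx == k)[0]
        size = members.size
        for a in range(size):
            for step in range(1, spec.lattice_degree // 2 + 1):
                i, j = members[a], members[(a + step) % size]
                if i == j or i in hub_set or j in hub_set:
                    continue
                p[i, j] = p[j, i] = pw
    hv = spec.hub_partial * spec.hub_scale
    non_hubs = [i for i in range(n) if i not in hub_set]
    ptr = 0
    for h in hub_pos:
        partners = []
        while len(partners) < spec.hub_partners:
            cand = non_hubs[ptr % len(non_hubs)]
            ptr += 1
            if mod_idx[cand] != mod_idx[h]:
                partners.append(cand)
        p[h, partners] = hv
        p[partners, h] = hv
    n_hubs = len(hub_pos)
    for a in range(n_hubs):
        for step in range(1, spec.hub_ring // 2 + 1):
            i, j = hub_pos[a], hub_pos[(a + step) % n_hubs]
            p[i, j] = p[j, i] = hv
    return p


def plant_ggm_covariance(spec: GGMCohortSpec) -> np.ndarray:
    """Covariance whose partial correlations follow the planted pattern."""
    p = planted_partial_matrix(spec)
    n = p.shape[0]
    precision = np.eye(n) - p
    smallest = float(np.linalg.eigvalsh(precision).min())
    if smallest <= 0:
        raise DefinitenessError(
            f"planted precision is not positive definite "
            f"(smallest eigenvalue {smallest:.6g}); reduce link strengths"
        )
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    beta = spec.global_corr
    cov = (1.0 - beta) * cov + beta  # shared global component
    np.fill_diagonal(cov, 1.0)
    return cov * spec.noise_sd**2


# ---------------------------------------------------------------------------
# sampling


def generate_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int,
    roi_labels: list[str] | None = None,
    tr_s: float = DEFAULT_TR_S,
) -> ROITimeSeries:
    """Sample a zero-mean multivariate normal series; reproducible per seed."""
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n):
        raise ConfigError(f"covariance must be square, got {cov.shape}")
    if n_timepoints < 2:
        raise ConfigError("n_timepoints must be >= 2")
    if roi_labels is not None and len(roi_labels) != n:
        raise ConfigError(
            f"label count ({len(roi_labels)}) does not match covariance size ({n})"
        )
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DefinitenessError("covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_timepoints, n)) @ chol.T
    columns = roi_labels if roi_labels is not None else [f"roi_{i}" for i in range(n)]
    return ROITimeSeries(pd.DataFrame(x, columns=columns), tr_s)


def generate_motion_trace(
    n_timepoints: int,
    exceeds_threshold: bool = False,
    seed: int = 0,
    limit: float = 2.0,
) -> MotionTrace:
    """Smooth rigid-body motion trace.

    A bounded random walk kept strictly below the exclusion limits, with a
    single super-threshold excursion injected when ``exceeds_threshold``.
    """
    if n_timepoints < 1:
        raise ConfigError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 0.02, size=(n_timepoints, 6))
    walk = np.cumsum(steps, axis=0)
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= min(1.0, 0.6 * limit / peak)  # stay well below the limit
    if exceeds_threshold:
        col = int(rng.integers(0, 6))
        row = int(rng.integers(n_timepoints // 2, n_timepoints))
        walk[row, col] = 1.25 * limit
    return MotionTrace(pd.DataFrame(walk, columns=list(MOTION_COLUMNS)))


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size * 4)
        keep = draw[(draw > low) & (draw < high)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _sample_demographics(group: str, size: int, params: dict, rng) -> pd.DataFrame:
    patient = group in ("PCD", "PNCD")
    age = _truncated_normal(rng, *params["age"], 60.0 if patient else 55.0, 90.0, size)
    edu = _truncated_normal(rng, *params["education_years"], 8.0, 22.0, size)
    pta_bounds = (25.2, 70.0) if patient else (0.0, 24.8)
    pta_l = _truncated_normal(rng, *params["pta_left"], *pta_bounds, size)
    pta_r = _truncated_normal(rng, *params["pta_right"], *pta_bounds, size)
    moca_bounds = (17.6, 25.4) if group == "PCD" else (25.6, 30.4)
    moca = np.round(_truncated_normal(rng, *params["moca"], *moca_bounds, size))
    moca = np.clip(moca, 18 if group == "PCD" else 26, 25 if group == "PCD" else 30)
    # exact male/female counts; scaled proportionally for non-default sizes
    if size == params["n_total"]:
        n_male = params["n_male"]
    else:
        n_male = int(round(params["n_male"] / params["n_total"] * size))
    sex = np.array(["M"] * n_male + ["F"] * (size - n_male))
    return pd.DataFrame(
        {
            "group": group,
            "age": np.round(age, 1),
            "sex": sex,
            "education_years": np.round(edu, 1),
            "pta_left": np.round(pta_l, 1),
            "pta_right": np.round(pta_r, 1),
            "moca": moca.astype(int),
        }
    )


@dataclass
class CohortConfig:
    """Everything needed to synthesize a cohort, including the seed."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_timepoints_acquired: int = DEFAULT_N_TIMEPOINTS
    tr_s: float = DEFAULT_TR_S
    structure: str = "ggm"  # "ggm" or "blocks"
    group_effect: dict[str, dict[str, float]] | None = None
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    motion_exceed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ConfigError("all group sizes must be >= 2")
        if self.n_timepoints_acquired < 20:
            raise ConfigError("n_timepoints_acquired must exceed the discarded volumes")
        if self.structure not in ("ggm", "blocks"):
            raise ConfigError(f"unknown structure {self.structure!r}")
        if not (0.0 <= self.motion_exceed_fraction <= 1.0):
            raise ConfigError("motion_exceed_fraction must be in [0, 1]")
        unknown = set(self.group_sizes) - set(self.demographics)
        if unknown:
            raise ConfigError(f"no demographics for groups: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "n_timepoints_acquired": self.n_timepoints_acquired,
            "tr_s": self.tr_s,
            "structure": self.structure,
            "group_effect": self.group_effect,
            "motion_exceed_fraction": self.motion_exceed_fraction,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "seed" not in data:
            raise ConfigError("serialized cohort config must carry a seed")
        return cls(**data)


@dataclass
class Cohort:
    roster: pd.DataFrame
    timeseries: dict[str, ROITimeSeries]
    motion: dict[str, MotionTrace]
    config: CohortConfig

    @property
    def n_subjects(self) -> int:
        return len(self.roster)

    def write(self, directory) -> None:
        """TSV time series and motion traces, CSV roster, YAML config."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(directory / "roster.csv", index=False)
        self.config.to_yaml(directory / "cohort_config.yaml")
        for sid, ts in self.timeseries.items():
            ts.values.to_csv(directory / f"{sid}_timeseries.tsv", sep="\t", index=False)
        for sid, trace in self.motion.items():
            trace.values.to_csv(directory / f"{sid}_motion.tsv", sep="\t", index=False)


def group_covariance(config: CohortConfig, group: str) -> np.ndarray:
    """The planted covariance for one group under the configured effect."""
    if config.structure == "blocks":
        return plant_covariance(CovarianceSpec())
    effect = (config.group_effect or {}).get(group, {})
    spec = GGMCohortSpec().with_effect(
        within_scale=effect.get("within_scale", 1.0),
        hub_scale=effect.get("hub_scale", 1.0),
    )
    return plant_ggm_covariance(spec)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Roster, ROI time series and motion trace for every subject.

    A single seed fans out deterministically: one substream per group for
    demographics and one per subject for the time series and motion trace.
    """
    labels = list(_default_partition_map())
    root = np.random.SeedSequence(config.seed)
    group_names = list(config.group_sizes)
    demo_seeds = root.spawn(len(group_names))
    rosters = []
    for g, ss in zip(group_names, demo_seeds):
        frame = _sample_demographics(
            g, config.group_sizes[g], config.demographics[g], np.random.default_rng(ss)
        )
        rosters.append(frame)
    roster = pd.concat(rosters, ignore_index=True)
    roster.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(roster))])

    covariances = {g: group_covariance(config, g) for g in group_names}
    n_exceed = {
        g: int(round(config.motion_exceed_fraction * config.group_sizes[g]))
        for g in group_names
    }
    seen = dict.fromkeys(group_names, 0)
    timeseries: dict[str, ROITimeSeries] = {}
    motion: dict[str, MotionTrace] = {}
    subject_seeds = root.spawn(len(roster))
    for (_, row), ss in zip(roster.iterrows(), subject_seeds):
        sid, g = row["subject_id"], row["group"]
        ts_seed, mo_seed = ss.generate_state(2) % (2**31)
        timeseries[sid] = generate_timeseries(
            covariances[g],
            config.n_timepoints_acquired,
            seed=int(ts_seed),
            roi_labels=labels,
            tr_s=config.tr_s,
        )
        exceeds = seen[g] < n_exceed[g]
        seen[g] += 1
        motion[sid] = generate_motion_trace(
            config.n_timepoints_acquired, exceeds_threshold=exceeds, seed=int(mo_seed)
        )
    return Cohort(roster=roster, timeseries=timeseries, motion=motion, config=config)


def roster_to_json(roster: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(roster.to_dict(orient="records"), fh, indent=1)
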