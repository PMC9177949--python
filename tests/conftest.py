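import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from presbynet.network import BinaryGraph, build_threshold_series, partial_correlation_matrix, sparsity_grid
from presbynet.preprocess import ROITimeSeries, regress_nuisance, NuisanceSet, global_mean_signal
from presbynet.synthetic import (
    CovarianceSpec,
    GGMCohortSpec,
    generate_timeseries,
    plant_covariance,
    plant_ggm_covariance,
)


def graph_from_adjacency(adj, sparsity=0.5, labels=None):
    return BinaryGraph(np.asarray(adj, dtype=np.uint8), sparsity, labels)


def subject_threshold_series(cov, seed, labels, grid=None, n_timepoints=220):
    """Generator -> global-mean regression -> partial correlation -> graphs.

    The analysis chain used for planted-structure recovery: the temporal
    filter is omitted because the synthetic signals are white-spectrum (see
    the methods note).
    """
    ts = generate_timeseries(cov, n_timepoints, seed=seed, roi_labels=labels)
    conf = NuisanceSet(global_mean_signal(ts).to_frame())
    cleaned = regress_nuisance(ts, conf)
    conn = partial_correlation_matrix(cleaned, rank_policy="pseudoinverse")
    return build_threshold_series(conn, grid if grid is not None else sparsity_grid())


@pytest.fixture(scope="session")
def block_spec():
    return CovarianceSpec()


@pytest.fixture(scope="session")
def block_cov(block_spec):
    return plant_covariance(block_spec)


@pytest.fixture(scope="session")
def ggm_spec():
    return GGMCohortSpec()


@pytest.fixture(scope="session")
def ggm_cov(ggm_spec):
    return plant_ggm_covariance(ggm_spec)


@pytest.fixture(scope="session")
def atlas_labels(block_spec):
    return list(block_spec.partition)


@pytest.fixture(scope="session")
def block_cohort_profiles(block_cov, atlas_labels):
    """Per-group global metric curves (20-null ensembles) for a small
    block-covariance cohort: shared by the small-world and grid-trend
    checks."""
    from presbynet.metrics import global_metrics_over_grid

    profiles = {}
    for gi, group in enumerate(("PCD", "PNCD", "HC")):
        curves = []
        for j in range(2):
            series = subject_threshold_series(block_cov, seed=1000 * gi + j, labels=atlas_labels)
            prof = global_metrics_over_grid(series, n_null=20, seed=17 * gi + j)
            curves.append(prof.curves)
        profiles[group] = sum(curves) / len(curves)
    return profiles


@pytest.fixture
def toy_roster():
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(9)],
            "group": ["PCD"] * 3 + ["PNCD"] * 3 + ["HC"] * 3,
            "age": [63, 61, 65, 62, 60, 64, 61, 62, 60],
            "sex": ["M", "F", "M", "F", "M", "F", "M", "F", "F"],
            "education_years": [10, 11, 9, 12, 11, 10, 11, 10, 12],
        }
    )
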