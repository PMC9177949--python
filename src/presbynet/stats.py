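"""Three-group statistics for demographics and network metrics.

The flow mirrors the clinical-study convention: Shapiro-Wilk normality
screen per group; one-way ANOVA for normally distributed continuous
variables, Kruskal-Wallis otherwise; Pearson chi-squared for categorical
tables; pairwise post-hoc comparisons (only after a significant omnibus)
via a linear model with a group indicator and age/sex/education covariates,
which without covariates reduces exactly to the pooled two-sample t-test;
Bonferroni correction over the nodal family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUPS = ("PCD", "PNCD", "HC")
DEFAULT_ALPHA = 0.05
PTA_NORMAL_LIMIT_DB = 25.0
MOCA_NORMAL_MIN = 26


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {g: values[groups == g] for g in pd.unique(groups)}


def normality_screen(values, groups, alpha: float = DEFAULT_ALPHA) -> dict:
    """Shapiro-Wilk p per group; the variable is non-normal if any p < alpha."""
    by_group = _group_arrays(values, groups)
    pvals = {}
    for g, arr in by_group.items():
        if arr.size < 3:
            raise StatsError(f"group {g!r} has n={arr.size} < 3; Shapiro-Wilk undefined")
        pvals[str(g)] = float(sps.shapiro(arr).pvalue)
    return {"p_values": pvals, "normal": all(p >= alpha for p in pvals.values())}


def omnibus_compare(values, groups, normal: bool) -> tuple[str, float, float]:
    """One-way ANOVA when normal, Kruskal-Wallis otherwise.

    Returns (test name, statistic, p).
    """
    by_group = list(_group_arrays(values, groups).values())
    if len(by_group) < 2 or any(a.size < 2 for a in by_group):
        raise StatsError("omnibus test needs >= 2 groups with n >= 2 each")
    if normal:
        res = sps.f_oneway(*by_group)
        return "anova", float(res.statistic), float(res.pvalue)
    res = sps.kruskal(*by_group)
    return "kruskal", float(res.statistic), float(res.pvalue)


def summary_stat_anova(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA from per-group summary statistics.

    Uses the classical between/within sum-of-squares decomposition; agrees
    with the raw-data ANOVA whenever the summaries are exact, which lets
    printed demographic tables serve as worked examples.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.size
    if k < 2 or (ns < 2).any():
        raise StatsError("summary ANOVA needs >= 2 groups with n >= 2 each")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), (0.0 if ss_between > 0 else 1.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def categorical_compare(contingency) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError("contingency table must be at least 2 x 2")
    expected = sps.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise StatsError("all expected counts must be positive")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def pairwise_posthoc(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-group comparisons adjusted for covariates.

    For each group pair, fits value ~ intercept + group_indicator +
    covariates by OLS and reports the t and p of the group-indicator
    coefficient.  With no covariates this is algebraically the pooled
    two-sample t-test.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        if len(covariates) != values.size:
            raise StatsError("covariate rows must match value count")
    group_names = list(pd.unique(groups))
    pairs = pairs or list(combinations(group_names, 2))
    rows = []
    for a, b in pairs:
        mask = np.isin(groups, (a, b))
        n_cov = 0 if covariates is None else covariates.shape[1]
        if mask.sum() <= n_cov + 2:
            raise StatsError(f"pair ({a}, {b}) has too few subjects for {n_cov} covariates")
        indicator = (groups[mask] == b).astype(float)
        design = pd.DataFrame({"group": indicator})
        if covariates is not None:
            design = pd.concat([design, covariates.loc[mask].reset_index(drop=True)], axis=1)
        model = sm.OLS(values[mask], sm.add_constant(design)).fit()
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "estimate": float(model.params["group"]),
                "t": float(model.tvalues["group"]),
                "p": float(model.pvalues["group"]),
                "df": float(model.df_resid),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def bonferroni_adjust(pvals, alpha: float = DEFAULT_ALPHA, m: int | None = None) -> pd.DataFrame:
    """Adjusted p = min(1, p * m); significant iff adjusted p < alpha."""
    pvals = np.asarray(pvals, dtype=float)
    family = int(m) if m is not None else pvals.size
    if family < 1:
        raise StatsError("family size must be >= 1")
    adjusted = np.minimum(1.0, pvals * family)
    return pd.DataFrame(
        {
            "p_raw": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < alpha,
            "family_size": family,
        }
    )


def classify_subjects(roster: pd.DataFrame) -> pd.Series:
    """Apply the clinical grouping rules to a subject roster.

    Presbycusis iff better-ear pure-tone average > 25 dB HL; among
    patients, PCD iff MoCA < 26, else PNCD; everyone else HC.
    """
    required = {"pta_left", "pta_right", "moca"}
    if not required <= set(roster.columns):
        raise StatsError(f"roster needs columns {sorted(required)}")
    if roster[list(required)].isna().any().any():
        raise StatsError("roster has missing PTA or MoCA entries")
    better_ear = roster[["pta_left", "pta_right"]].min(axis=1)
    patient = better_ear > PTA_NORMAL_LIMIT_DB
    decline = roster["moca"] < MOCA_NORMAL_MIN
    out = pd.Series("HC", index=roster.index, name="group")
    out[patient & decline] = "PCD"
    out[patient & ~decline] = "PNCD"
    return out


@dataclass
class GroupComparisonReport:
    """Omnibus, post-hoc and corrected statistics for a family of variables."""

    rows: pd.DataFrame
    posthoc: pd.DataFrame
    alpha: float
    covariates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "covariates": self.covariates,
            "omnibus": self.rows.to_dict(orient="records"),
            "posthoc": self.posthoc.to_dict(orient="records"),
        }


def compare_metric_groups(
    table: pd.DataFrame,
    roster: pd.DataFrame,
    value_columns: list[str],
    alpha: float = DEFAULT_ALPHA,
    covariate_columns: tuple[str, ...] = ("age", "sex", "education_years"),
    bonferroni_m: int | None = None,
) -> GroupComparisonReport:
    """Full statistical flow for a family of metric columns.

    ``table`` holds one row per subject with the metric columns and a
    ``subject_id``; ``roster`` supplies group and covariates.  Post-hoc
    tests run only for variables whose omnibus p < alpha; the Bonferroni
    family defaults to the number of variables tested (e.g. 90 nodes).
    """
    merged = table.merge(
        roster[["subject_id", "group"] + [c for c in covariate_columns if c in roster.columns]],
        on="subject_id",
        validate="one_to_one",
    )
    covs = merged[[c for c in covariate_columns if c in merged.columns]].copy()
    if "sex" in covs.columns and covs["sex"].dtype == object:
        covs["sex"] = (covs["sex"] == "M").astype(float)
    groups = merged["group"].to_numpy()

    omnibus_rows = []
    posthoc_rows = []
    family = bonferroni_m if bonferroni_m is not None else len(value_columns)
    for col in value_columns:
        values = merged[col].to_numpy(dtype=float)
        screen = normality_screen(values, groups, alpha)
        test, stat, p = omnibus_compare(values, groups, screen["normal"])
        omnibus_rows.append(
            {
                "variable": col,
                "test": test,
                "statistic": stat,
                "p": p,
                "normal": screen["normal"],
            }
        )
        if p < alpha:
            ph = pairwise_posthoc(values, groups, covariates=covs)
            ph.insert(0, "variable", col)
            posthoc_rows.append(ph)
    posthoc = (
        pd.concat(posthoc_rows, ignore_index=True)
        if posthoc_rows
        else pd.DataFrame(columns=["variable", "group_a", "group_b", "t", "p", "df", "n"])
    )
    if len(posthoc):
        adj = bonferroni_adjust(posthoc["p"].to_numpy(), alpha=alpha, m=family)
        posthoc["p_adjusted"] = adj["p_adjusted"].to_numpy()
        posthoc["significant"] = adj["significant"].to_numpy()
        posthoc["family_size"] = family
    return GroupComparisonReport(
        rows=pd.DataFrame(omnibus_rows),
        posthoc=posthoc,
        alpha=alpha,
        covariates=[c for c in covariate_columns if c in merged.columns],
    )
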