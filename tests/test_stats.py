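"""Group statistics: normality gate, omnibus tests, worked demographic
examples, covariate-adjusted post-hocs and Bonferroni correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from presbynet.stats import (
    StatsError,
    bonferroni_adjust,
    categorical_compare,
    classify_subjects,
    compare_metric_groups,
    normality_screen,
    omnibus_compare,
    pairwise_posthoc,
    summary_stat_anova,
)

# published demographic summaries: (mean, sd) per group with n = 30/30/50
AGE_ROW = ([63.03, 62.47, 61.08], [7.30, 7.12, 3.93], [30, 30, 50])
EDU_ROW = ([10.40, 11.47, 10.78], [2.18, 1.72, 1.79], [30, 30, 50])
SEX_TABLE = [[14, 12, 24], [16, 18, 26]]


class TestNormalityScreen:
    def test_exact_normal_scores_flagged_normal(self):
        scores = sps.norm.ppf(np.linspace(0.01, 0.99, 50))
        values = np.concatenate([scores, scores, scores])
        groups = np.repeat(["a", "b", "c"], 50)
        assert normality_screen(values, groups)["normal"]

    def test_skewed_samples_flagged_non_normal(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            values = rng.exponential(size=100)
            groups = np.repeat(["a", "b"], 50)
            if not normality_screen(values, groups)["normal"]:
                hits += 1
        assert hits >= 95

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            normality_screen([1.0, 2.0, 3.0, 4.0, 5.0], ["a", "a", "a", "b", "b"])


class TestOmnibus:
    def test_identical_groups_give_null_result(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        test, stat, p = omnibus_compare(values, groups, normal=True)
        assert test == "anova"
        assert abs(stat) < 1e-12 and p > 0.999

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)])
        groups = np.array(["a"] * 20 + ["b"] * 25)
        _, f, p_f = omnibus_compare(values, groups, normal=True)
        t, p_t = sps.ttest_ind(values[:20], values[20:])
        assert abs(f - t**2) < 1e-10
        assert abs(p_f - p_t) < 1e-12

    def test_nonparametric_route(self):
        rng = np.random.default_rng(1)
        values = rng.exponential(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        test, stat, p = omnibus_compare(values, groups, normal=False)
        assert test == "kruskal" and 0 <= p <= 1

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        relabel = {"a": "c", "b": "a", "c": "b"}
        _, s1, p1 = omnibus_compare(values, groups, normal=True)
        _, s2, p2 = omnibus_compare(values, np.vectorize(relabel.get)(groups), normal=True)
        assert abs(s1 - s2) < 1e-12 and abs(p1 - p2) < 1e-12


class TestSummaryAnova:
    def test_equal_means_zero_f(self):
        f, p = summary_stat_anova([5.0, 5.0, 5.0], [1.0, 1.2, 0.9], [10, 12, 15])
        assert f == 0.0 and p == 1.0

    def test_published_age_row(self):
        _, p = summary_stat_anova(*AGE_ROW)
        assert abs(p - 0.321) < 0.005

    def test_published_education_row(self):
        _, p = summary_stat_anova(*EDU_ROW)
        assert abs(p - 0.087) < 0.005

    def test_agrees_with_raw_data_anova(self):
        rng = np.random.default_rng(3)
        samples = [rng.normal(m, 1.0, size=n) for m, n in [(0, 12), (0.3, 15), (0.6, 9)]]
        means = [s.mean() for s in samples]
        sds = [s.std(ddof=1) for s in samples]
        ns = [len(s) for s in samples]
        f_sum, p_sum = summary_stat_anova(means, sds, ns)
        raw = sps.f_oneway(*samples)
        assert abs(f_sum - raw.statistic) < 1e-10
        assert abs(p_sum - raw.pvalue) < 1e-10


class TestCategorical:
    def test_published_sex_table(self):
        chi2, p = categorical_compare(SEX_TABLE)
        assert abs(p - 0.776) < 0.005

    def test_proportional_table_null(self):
        chi2, p = categorical_compare([[10, 20, 30], [5, 10, 15]])
        assert abs(chi2) < 1e-12 and p == 1.0

    def test_two_by_two_matches_hand_formula(self):
        table = np.array([[12.0, 7.0], [9.0, 14.0]])
        chi2, _ = categorical_compare(table)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert abs(chi2 - by_hand) < 1e-10


class TestPairwisePosthoc:
    def test_reduces_to_pooled_t_without_covariates(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 18)])
        groups = np.array(["a"] * 15 + ["b"] * 18)
        row = pairwise_posthoc(values, groups).iloc[0]
        t, p = sps.ttest_ind(values[15:], values[:15])  # indicator codes b = 1
        assert abs(row["t"] - t) < 1e-10 and abs(row["p"] - p) < 1e-10

    def test_outcome_as_covariate_absorbs_group_effect(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
        groups = np.array(["a"] * 20 + ["b"] * 20)
        cov = pd.DataFrame({"same": values})
        row = pairwise_posthoc(values, groups, covariates=cov).iloc[0]
        # the confound absorbs the whole group difference
        assert abs(row["estimate"]) < 1e-10
        assert row["p"] > 0.05

    def test_adjustment_gains_power_with_correlated_covariate(self):
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            covariate = rng.normal(size=40)
            noise = rng.normal(size=40)
            groups = np.array(["a"] * 20 + ["b"] * 20)
            effect = (groups == "b").astype(float) * 0.8
            values = effect + 2.0 * covariate + 0.5 * noise
            unadjusted = pairwise_posthoc(values, groups).iloc[0]["p"]
            adjusted = pairwise_posthoc(
                values, groups, covariates=pd.DataFrame({"c": covariate})
            ).iloc[0]["p"]
            wins += adjusted < unadjusted
        assert wins >= 40  # >= 80 % of replicates

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatsError):
            pairwise_posthoc(
                [1.0, 2.0, 3.0, 4.0],
                ["a", "a", "b", "b"],
                covariates=pd.DataFrame({"c1": np.zeros(4), "c2": np.ones(4)}),
            )


class TestBonferroni:
    def test_large_family_kills_moderate_p(self):
        out = bonferroni_adjust([0.01], m=90)
        assert abs(out.loc[0, "p_adjusted"] - 0.9) < 1e-12
        assert not out.loc[0, "significant"]

    def test_family_of_one_is_identity(self):
        out = bonferroni_adjust([0.03], m=1)
        assert out.loc[0, "p_adjusted"] == 0.03 and bool(out.loc[0, "significant"])

    def test_equivalent_to_alpha_over_m_rule(self):
        rng = np.random.default_rng(6)
        pvals = rng.uniform(size=200)
        out = bonferroni_adjust(pvals, alpha=0.05, m=200)
        brute = pvals < 0.05 / 200
        assert np.array_equal(out["significant"].to_numpy(), brute)


class TestClassifySubjects:
    @pytest.mark.parametrize(
        "pta_l,pta_r,moca,expected",
        [
            (20.0, 22.0, 28, "HC"),       # normal hearing
            (33.0, 35.0, 24, "PCD"),      # better ear 33 > 25, MoCA < 26
            (30.0, 28.0, 26, "PNCD"),     # boundary MoCA 26 is normal cognition
            (26.0, 24.0, 20, "HC"),       # better ear 24 <= 25: no hearing loss
        ],
    )
    def test_rule_application(self, pta_l, pta_r, moca, expected):
        roster = pd.DataFrame(
            {"pta_left": [pta_l], "pta_right": [pta_r], "moca": [moca]}
        )
        assert classify_subjects(roster).iloc[0] == expected

    def test_missing_fields_rejected(self):
        roster = pd.DataFrame({"pta_left": [30.0], "pta_right": [np.nan], "moca": [25]})
        with pytest.raises(StatsError):
            classify_subjects(roster)


class TestCompareMetricGroups:
    def test_posthoc_only_after_significant_omnibus(self, toy_roster):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "subject_id": toy_roster["subject_id"],
                "null_metric": rng.normal(size=9),
                "shifted_metric": np.where(toy_roster["group"] == "PCD", 30.0, 0.0)
                + rng.normal(size=9),
            }
        )
        report = compare_metric_groups(table, toy_roster, ["null_metric", "shifted_metric"])
        tested = set(report.posthoc["variable"])
        significant_omnibus = set(
            report.rows.loc[report.rows["p"] < report.alpha, "variable"]
        )
        assert tested == significant_omnibus
        assert "covariates" not in tested

    def test_report_serializable(self, toy_roster):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {"subject_id": toy_roster["subject_id"], "m": rng.normal(size=9)}
        )
        report = compare_metric_groups(table, toy_roster, ["m"])
        out = report.to_dict()
        assert set(out) == {"alpha", "covariates", "omnibus", "posthoc"}
        assert out["covariates"] == ["age", "sex", "education_years"]
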