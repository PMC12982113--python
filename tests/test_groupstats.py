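"""Group statistics: TANOVA, mixed ANOVA, gated pairwise tests, clinical tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from easleep.groupstats import (
    StatResult,
    StatsError,
    bonferroni,
    clinical_change_tests,
    demographic_tests,
    metric_anova,
    posthoc_pairwise,
    results_table,
    tanova_by_class,
    tanova_permutation,
    transition_tests,
)
from easleep.synthgen import CohortSpec, simulate_cohort


def _subject_maps(template, n, noise, rng):
    maps = template + rng.normal(size=(n, template.size)) * noise
    return maps


class TestTanova:
    def test_null_groups_give_large_p(self, archetypes):
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(10):
            a = _subject_maps(archetypes.maps[0], 10, 0.1, rng)
            b = _subject_maps(archetypes.maps[0], 10, 0.1, rng)
            r = tanova_permutation({"HC": a, "CI": b}, n_perm=199, seed=rep)
            ps.append(r.p_raw)
        assert np.median(ps) > 0.2

    def test_planted_difference_detected(self, archetypes):
        rng = np.random.default_rng(1)
        a = _subject_maps(archetypes.maps[0], 15, 0.1, rng)
        b = _subject_maps(archetypes.maps[3], 15, 0.1, rng)  # |r| truth < 0.5
        r = tanova_permutation({"HC": a, "CI": b}, n_perm=999, seed=2)
        assert r.p_raw <= 0.01

    def test_within_group_subject_order_irrelevant(self, archetypes):
        rng = np.random.default_rng(3)
        a = _subject_maps(archetypes.maps[1], 8, 0.2, rng)
        b = _subject_maps(archetypes.maps[1], 8, 0.2, rng)
        r1 = tanova_permutation({"HC": a, "CI": b}, n_perm=99, seed=5)
        r2 = tanova_permutation({"HC": a[::-1], "CI": b[::-1]}, n_perm=99, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_small_group_rejected(self, archetypes):
        with pytest.raises(StatsError, match="fewer than 2"):
            tanova_permutation({"HC": archetypes.maps[:1], "CI": archetypes.maps[:2]},
                               n_perm=100)

    def test_by_class_adjusts_over_four_classes(self, archetypes):
        rng = np.random.default_rng(4)
        gm = {
            c: {"HC": _subject_maps(archetypes.maps[i], 5, 0.3, rng),
                "CI": _subject_maps(archetypes.maps[i], 5, 0.3, rng)}
            for i, c in enumerate("ABCD")
        }
        results = tanova_by_class(gm, n_perm=99, seed=0)
        assert len(results) == 4
        for r in results:
            assert r.family_size == 4
            assert r.p_adjusted == pytest.approx(min(1.0, 4 * r.p_raw))


def _mixed_anova_bruteforce(df):
    """Cell-means sums-of-squares for a balanced 2-group x 2-class design."""
    groups = sorted(df["group"].unique())
    classes = sorted(df["class"].unique())
    n = df[df["group"] == groups[0]]["subject_id"].nunique()
    b = len(classes)
    gm = df["value"].mean()
    m_g = {g: df[df["group"] == g]["value"].mean() for g in groups}
    m_b = {c: df[df["class"] == c]["value"].mean() for c in classes}
    m_gb = {(g, c): df[(df["group"] == g) & (df["class"] == c)]["value"].mean()
            for g in groups for c in classes}
    subj_mean = df.groupby(["group", "subject_id"])["value"].mean()
    ss_group = n * b * sum((m_g[g] - gm) ** 2 for g in groups)
    ss_subj = b * sum((subj_mean[g, s] - m_g[g]) ** 2
                      for g in groups for s in subj_mean[g].index)
    ss_class = n * len(groups) * sum((m_b[c] - gm) ** 2 for c in classes)
    ss_int = n * sum((m_gb[g, c] - m_g[g] - m_b[c] + gm) ** 2
                     for g in groups for c in classes)
    ss_tot = ((df["value"] - gm) ** 2).sum()
    ss_err = ss_tot - ss_group - ss_subj - ss_class - ss_int
    df_group, df_subj = len(groups) - 1, len(groups) * (n - 1)
    df_class, df_int = b - 1, (len(groups) - 1) * (b - 1)
    df_err = len(groups) * (n - 1) * (b - 1)
    return {
        "group": (ss_group / df_group) / (ss_subj / df_subj),
        "class": (ss_class / df_class) / (ss_err / df_err),
        "interaction": (ss_int / df_int) / (ss_err / df_err),
    }


def _toy_mixed(seed, n=8):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("HC", "CI"):
        for s in range(n):
            base = rng.normal()
            for c in ("A", "B"):
                shift = 0.5 if (g == "CI" and c == "B") else 0.0
                rows.append({"subject_id": f"{g}{s}", "group": g, "class": c,
                             "value": base + shift + rng.normal()})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_bruteforce_cell_means(self):
        df = _toy_mixed(0)
        results = {r.effect_name.split(":")[1]: r for r in metric_anova(df, "toy")}
        expected = _mixed_anova_bruteforce(df)
        for eff in ("group", "class", "interaction"):
            assert results[eff].statistic == pytest.approx(expected[eff], abs=1e-9)

    def test_interaction_f_equals_squared_t_of_difference_scores(self):
        df = _toy_mixed(1)
        results = {r.effect_name.split(":")[1]: r for r in metric_anova(df, "toy")}
        wide = df.pivot_table(index=["subject_id", "group"], columns="class",
                              values="value").reset_index()
        diff = wide["A"] - wide["B"]
        t = sps.ttest_ind(diff[wide["group"] == "HC"], diff[wide["group"] == "CI"])
        assert results["interaction"].statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_zero_variance_input_yields_no_effect_result(self):
        rows = [{"subject_id": f"s{s}", "group": g, "class": c, "value": 1.0}
                for g in ("HC", "CI") for s in range(4) for c in ("A", "B")]
        results = metric_anova(pd.DataFrame(rows), "flat")
        assert all(r.p_adjusted == 1.0 for r in results)

    def test_missing_cells_listed(self):
        df = _toy_mixed(2)
        df = df.drop(df[(df["subject_id"] == "HC0") & (df["class"] == "B")].index)
        with pytest.raises(StatsError, match="HC0"):
            metric_anova(df, "toy")


class TestPosthoc:
    def test_sample_against_itself_is_null(self):
        x = np.random.default_rng(0).normal(size=20)
        r = posthoc_pairwise({"a": x, "b": x}, [("a", "b")], paired=True)[0]
        assert r.statistic == 0.0
        assert r.p_adjusted == 1.0

    def test_planted_shift_detected_in_most_repeats(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            a = rng.normal(size=41)
            b = rng.normal(loc=1.0, size=41)  # 1 SD shift at the cohort size
            r = posthoc_pairwise({"a": a, "b": b}, [("a", "b")], paired=False,
                                 family_size=4)[0]
            hits += r.p_adjusted < 0.05
        assert hits >= 18

    def test_bonferroni_family_of_12(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r = posthoc_pairwise({"a": a, "b": b}, [("a", "b")], paired=False,
                             family_size=12)[0]
        assert r.p_adjusted == pytest.approx(min(1.0, 12 * r.p_raw))
        assert r.family_size == 12

    def test_dunn_backend_agrees_with_rank_direction(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=30)
        b = rng.normal(loc=2.0, size=30)
        r = posthoc_pairwise({"a": a, "b": b}, [("a", "b")], paired=False,
                             backend="dunn")[0]
        assert r.test_name == "dunn"
        assert r.statistic < 0  # a ranks below b
        assert r.p_adjusted < 0.05

    def test_tiny_sample_rejected(self):
        with pytest.raises(StatsError, match="n >= 3"):
            posthoc_pairwise({"a": np.ones(2), "b": np.ones(5)}, [("a", "b")],
                             paired=False)


class TestTransitions:
    def test_twelve_tests_with_family_twelve(self):
        rng = np.random.default_rng(0)
        pre = rng.random((10, 4, 4)) * 10
        post = rng.random((10, 4, 4)) * 10
        results = transition_tests(pre, post)
        assert len(results) == 12
        assert all(r.family_size == 12 for r in results)

    def test_identical_pre_post_all_null(self):
        rng = np.random.default_rng(1)
        pre = rng.random((8, 4, 4)) * 10
        results = transition_tests(pre, pre.copy())
        assert all(r.p_adjusted == 1.0 for r in results)

    def test_planted_transition_shift_flagged(self):
        rng = np.random.default_rng(2)
        pre = 8.0 + rng.normal(size=(41, 4, 4))
        post = pre + rng.normal(size=(41, 4, 4)) * 0.3
        post[:, 1, 2] += 2.0  # > 1 SD planted increase of B->C
        post[:, 2, 1] += 2.0  # and C->B
        results = {r.effect_name: r for r in transition_tests(pre, post)}
        assert results["OrgTM_B->C"].p_adjusted < 0.05
        assert results["OrgTM_C->B"].p_adjusted < 0.05


class TestClinical:
    def test_no_change_is_null(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 2, size=12)
        table = pd.DataFrame({
            "group": ["CI"] * 12,
            **{f"{s}_pre": vals for s in ("PSQI",)},
            **{f"{s}_post": vals for s in ("PSQI",)},
        })
        r = clinical_change_tests(table, scales=("PSQI",))[0]
        assert r.p_adjusted == 1.0

    def test_planted_cohort_improvement_is_significant(self):
        cohort = simulate_cohort(CohortSpec(n_hc=3, n_ci=41, n_responders=14, seed=4))
        results = {r.effect_name: r for r in clinical_change_tests(cohort.table)}
        assert results["PSQI pre vs post"].p_raw < 0.001
        assert results["ISI pre vs post"].p_raw < 0.001

    def test_missing_scale_column_named(self):
        table = pd.DataFrame({"group": ["CI"] * 5, "PSQI_pre": np.arange(5) + 5.0})
        with pytest.raises(StatsError, match="PSQI_post"):
            clinical_change_tests(table, scales=("PSQI",))

    def test_equal_sex_proportions_null_chi_square(self):
        table = pd.DataFrame({
            "group": ["HC"] * 20 + ["CI"] * 40,
            "sex": (["M"] * 10 + ["F"] * 10) + (["M"] * 20 + ["F"] * 20),
        })
        r = demographic_tests(table)[0]
        assert r.test_name == "chi_square"
        assert r.p_raw == pytest.approx(1.0)


class TestResultContracts:
    def test_adjusted_p_clipped_and_consistent(self):
        with pytest.raises(StatsError):
            StatResult("t", "x", 1.0, 1.0, 0.5, 0.2, "bonferroni", 2)
        assert bonferroni(0.4, 12) == 1.0

    def test_results_table_round_trip(self):
        r = StatResult("t", "x", 1.0, 3.0, 0.5, 1.0, "bonferroni", 2,
                       {"HC": "1.0 ± 0.1"})
        df = results_table([r])
        assert df.loc[0, "effect"] == "x"
        assert df.loc[0, "summary[HC]"] == "1.0 ± 0.1"

    def test_permutation_pvalues_valid_under_null(self, archetypes):
        """P(p <= alpha) <= alpha + 1/(n_perm+1) under exchangeability."""
        rng = np.random.default_rng(9)
        alpha, n_perm, reps = 0.05, 99, 60
        hits = 0
        for rep in range(reps):
            a = _subject_maps(archetypes.maps[2], 6, 0.4, rng)
            b = _subject_maps(archetypes.maps[2], 6, 0.4, rng)
            r = tanova_permutation({"x": a, "y": b}, n_perm=n_perm, seed=rep)
            hits += r.p_raw <= alpha
        bound = alpha + 1.0 / (n_perm + 1)
        # binomial 3-sigma slack on top of the exactness bound
        assert hits <= reps * bound + 3 * np.sqrt(reps * bound * (1 - bound))
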