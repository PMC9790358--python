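import numpy as np
import pandas as pd
import pytest
from scipy import stats

from predinfer import (
    cohen_d_from_groups,
    cohen_d_from_t,
    correlate_with_covariates,
    kruskal_wallis_posthoc,
    mixed_anova_hf,
    rank_sum_test,
    route_two_sample_test,
    welch_james_adf,
    wilcoxon_r,
)

from oracles import kruskal_h_by_hand, ranksum_exact_p


def _long_table(groups, k, rng, group_sd=None, subject_sd=1.0, noise_sd=1.0,
                group_shift=0.0, within_shift=0.0):
    """Balanced-within mixed-design data: groups maps label -> n subjects."""
    rows = []
    sid = 0
    for gi, (label, n) in enumerate(groups.items()):
        sd = noise_sd if group_sd is None else group_sd[label]
        for _ in range(n):
            base = rng.normal(0, subject_sd) + gi * group_shift
            for w in range(k):
                rows.append({"subject_id": f"S{sid}", "group": label, "w": w,
                             "y": base + w * within_shift + rng.normal(0, sd)})
            sid += 1
    return pd.DataFrame(rows)


class TestRankSum:
    def test_identical_groups(self):
        res = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert abs(res.statistic) < 1e-12
        assert res.p_value == pytest.approx(1.0)

    def test_against_exact_enumeration_4v4(self, rng):
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.8, 1, 4)
            approx = rank_sum_test(a, b)
            exact = ranksum_exact_p(a, b)
            assert abs(approx.p_value - exact) < 0.06

    def test_power_under_large_shift(self, rng):
        rejections = 0
        for _ in range(200):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            rejections += rank_sum_test(a, b).p_value < 0.01
        assert rejections > 198

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([5, 5, 5], [5, 5, 5])

    def test_sign_follows_group_order(self):
        res = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert res.statistic < 0


class TestEffectSizes:
    def test_wilcoxon_r_worked_example(self):
        assert wilcoxon_r(-2.18, 73) == pytest.approx(0.26, abs=0.005)

    def test_cohen_d_worked_example(self):
        assert cohen_d_from_t(-2.12, 46, 27) == pytest.approx(0.51, abs=0.005)

    def test_wilcoxon_r_monotone_in_n(self):
        rs = [wilcoxon_r(2.0, n) for n in (10, 40, 160)]
        assert rs[0] > rs[1] > rs[2]
        assert wilcoxon_r(0.0, 50) == 0.0

    def test_d_variants_agree_for_student_t(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 1, 35)
        t, _ = stats.ttest_ind(a, b)
        assert cohen_d_from_t(t, 25, 35) == pytest.approx(
            cohen_d_from_groups(a, b), abs=1e-10)

    def test_equal_means_zero_d(self):
        a = np.array([1.0, 2, 3, 4])
        assert cohen_d_from_groups(a, a + 0) == 0.0


class TestMixedAnovaHF:
    def test_two_levels_no_correction(self, rng):
        df = _long_table({"A": 12, "B": 12}, 2, rng)
        out = mixed_anova_hf(df, "y", "w", "subject_id", "group")
        assert "eps=1.0000" in out["within"].correction
        df1, df2 = out["within"].df
        assert (df1, df2) == (1.0, 22.0)

    def test_compound_symmetry_matches_uncorrected_oracle(self, rng):
        """Under compound symmetry epsilon ~ 1 and the HF-corrected p matches
        the uncorrected F test."""
        df = _long_table({"A": 40, "B": 40}, 3, rng, subject_sd=2.0)
        out = mixed_anova_hf(df, "y", "w", "subject_id", "group")
        import pingouin as pg
        aov = pg.mixed_anova(data=df, dv="y", within="w", subject="subject_id",
                             between="group", correction=False).set_index("Source")
        wide = df.pivot(index="subject_id", columns="w", values="y")
        eps = min(float(pg.epsilon(wide, correction="hf")), 1.0)
        assert eps > 0.9
        assert out["within"].p_value == pytest.approx(
            float(aov.loc["w", "p_unc"]), abs=0.02)
        f_direct = stats.f.sf(float(aov.loc["w", "F"]),
                              eps * float(aov.loc["w", "DF1"]),
                              eps * float(aov.loc["w", "DF2"]))
        assert out["within"].p_value == pytest.approx(f_direct, abs=1e-6)

    def test_missing_cells_rejected(self, rng):
        df = _long_table({"A": 5, "B": 5}, 3, rng).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova_hf(df, "y", "w", "subject_id", "group")


class TestWelchJames:
    def test_reduces_to_welch_t_single_measure(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.7, 3, 23)
        rows = ([{"subject_id": f"A{i}", "group": "A", "w": 0, "y": v}
                 for i, v in enumerate(a)]
                + [{"subject_id": f"B{i}", "group": "B", "w": 0, "y": v}
                   for i, v in enumerate(b)])
        out = welch_james_adf(pd.DataFrame(rows), "y", "w", "subject_id", "group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert out["group"].statistic == pytest.approx(t**2, rel=1e-8)
        assert out["group"].p_value == pytest.approx(p, rel=1e-8)
        v1, v2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        welch_df = (v1 + v2) ** 2 / (v1**2 / (a.size - 1) + v2**2 / (b.size - 1))
        assert out["group"].df[1] == pytest.approx(welch_df, rel=1e-8)

    def test_agrees_with_mixed_anova_when_homoscedastic(self, rng):
        ps_wj, ps_aov = [], []
        for _ in range(60):
            df = _long_table({"A": 25, "B": 25}, 3, rng, within_shift=0.3)
            wj = welch_james_adf(df, "y", "w", "subject_id", "group")
            aov = mixed_anova_hf(df, "y", "w", "subject_id", "group")
            ps_wj.append(wj["within"].p_value < 0.05)
            ps_aov.append(aov["within"].p_value < 0.05)
        assert abs(np.mean(ps_wj) - np.mean(ps_aov)) < 0.15

    def test_fractional_df_reported(self, rng):
        df = _long_table({"A": 10, "B": 12}, 3, rng,
                         group_sd={"A": 1.0, "B": 3.0})
        out = welch_james_adf(df, "y", "w", "subject_id", "group")
        for eff in ("group", "within", "interaction"):
            q, df2 = out[eff].df
            assert df2 != int(df2) or df2 > 0
            assert 0 <= out[eff].p_value <= 1

    def test_three_group_interaction_df1(self, rng):
        df = _long_table({"A": 10, "B": 10, "C": 10}, 3, rng)
        out = welch_james_adf(df, "y", "w", "subject_id", "group")
        assert out["group"].df[0] == 2.0
        assert out["interaction"].df[0] == 4.0


class TestKruskalWallis:
    def test_identical_groups_high_p(self):
        vals = np.tile([1.0, 2, 3, 4, 5], 3)
        labels = np.repeat(["A", "B", "C"], 5)
        omnibus, _ = kruskal_wallis_posthoc(vals, labels)
        assert omnibus.p_value > 0.9

    def test_statistic_matches_hand_formula(self, rng):
        samples = [rng.normal(i, 1, 3) for i in range(3)]
        vals = np.concatenate(samples)
        labels = np.repeat(["A", "B", "C"], 3)
        omnibus, _ = kruskal_wallis_posthoc(vals, labels)
        assert omnibus.statistic == pytest.approx(kruskal_h_by_hand(samples),
                                                  rel=1e-10)

    def test_bonferroni_definition(self, rng):
        vals = rng.normal(size=18)
        labels = np.repeat(["A", "B", "C"], 6)
        _, posthocs = kruskal_wallis_posthoc(vals, labels)
        assert len(posthocs) == 3
        for res in posthocs:
            raw = rank_sum_test(vals[labels == res.label.split(" vs ")[0]],
                                vals[labels == res.label.split(" vs ")[1]]).p_value
            assert res.p_value == pytest.approx(min(1.0, 3 * raw))

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_posthoc([1.0, 2, 3, 4], ["A", "A", "B", "B"])


class TestCorrelations:
    def test_perfect_line(self):
        s = pd.DataFrame({"subject_id": list("abcde"),
                          "alpha": [1.0, 2, 3, 4, 5]})
        c = pd.DataFrame({"subject_id": list("abcde"),
                          "anxiety": [3.0, 5, 7, 9, 11]})
        out = correlate_with_covariates(s, c)
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # hand: r = sum((x-3)(y-3)) / sqrt(sum((x-3)^2) sum((y-3)^2)) = 8/10
        s = pd.DataFrame({"subject_id": list("abcde"), "m": x})
        c = pd.DataFrame({"subject_id": list("abcde"), "cov": y})
        out = correlate_with_covariates(s, c)
        assert out.r.iloc[0] == pytest.approx(0.8)

    def test_null_correlation_bounds(self, rng):
        hits = 0
        for _ in range(200):
            s = pd.DataFrame({"subject_id": np.arange(73),
                              "m": rng.normal(size=73)})
            c = pd.DataFrame({"subject_id": np.arange(73),
                              "cov": rng.normal(size=73)})
            hits += abs(correlate_with_covariates(s, c).r.iloc[0]) < 0.23
        assert 0.90 < hits / 200 <= 1.0

    def test_zero_variance_rejected(self):
        s = pd.DataFrame({"subject_id": list("abc"), "m": [1.0, 1, 1]})
        c = pd.DataFrame({"subject_id": list("abc"), "cov": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            correlate_with_covariates(s, c)


class TestRouting:
    def test_route_recorded_in_log(self, rng):
        log = []
        route_two_sample_test(rng.normal(size=20), rng.normal(size=20),
                              label="demo", log=log)
        assert len(log) == 1 and "demo" in log[0]

    def test_skewed_data_routes_to_ranksum(self, rng):
        routes = []
        for _ in range(50):
            a = rng.exponential(1, 40) ** 2
            b = rng.exponential(1, 40) ** 2
            routes.append(route_two_sample_test(a, b).test_name)
        assert sum(r == "wilcoxon_rank_sum" for r in routes) > 45
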