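import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from painmem import bonferroni, rm_anova_mixed, rm_anova_oneway, significance_report
from painmem.stats import AnovaResult, DesignError


# ---------------------------------------------------------------------------
# independent loop oracles: explicit sums of squares, no vectorization

def oneway_rm_f_loop(x):
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    ss_cond = n * sum((m - grand) ** 2 for m in col_means)
    ss_subj = k * sum((m - grand) ** 2 for m in row_means)
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def mixed_f_loop(x, group_of):
    """x: subject x time matrix; group_of: group label per subject row."""
    n, k = x.shape
    groups = sorted(set(group_of))
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    subj_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    time_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_between = k * sum((m - grand) ** 2 for m in subj_means)
    ss_group = 0.0
    for g in groups:
        idx = [i for i in range(n) if group_of[i] == g]
        gm = sum(subj_means[i] for i in idx) / len(idx)
        ss_group += k * len(idx) * (gm - grand) ** 2
    ss_subj_within = ss_between - ss_group
    ss_time = n * sum((m - grand) ** 2 for m in time_means)
    ss_cells = 0.0
    for g in groups:
        idx = [i for i in range(n) if group_of[i] == g]
        for j in range(k):
            cm = sum(x[i][j] for i in idx) / len(idx)
            ss_cells += len(idx) * (cm - grand) ** 2
    ss_int = ss_cells - ss_group - ss_time
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err_within = ss_total - ss_between - ss_time - ss_int
    g = len(groups)
    ms_sw = ss_subj_within / (n - g)
    ms_ew = ss_err_within / ((n - g) * (k - 1))
    return {
        "group": (ss_group / (g - 1)) / ms_sw,
        "time": (ss_time / (k - 1)) / ms_ew,
        "group x time": (ss_int / ((g - 1) * (k - 1))) / ms_ew,
    }


def long_table(x, conditions=None):
    n, k = x.shape
    conditions = conditions or [f"c{j}" for j in range(k)]
    rows = [
        (f"s{i}", conditions[j], x[i, j]) for i in range(n) for j in range(k)
    ]
    return pd.DataFrame(rows, columns=["subject", "condition", "value"])


def mixed_long_table(x, group_of, times=None):
    n, k = x.shape
    times = times or [f"t{j}" for j in range(k)]
    rows = [
        (f"s{i}", group_of[i], times[j], x[i, j])
        for i in range(n)
        for j in range(k)
    ]
    return pd.DataFrame(rows, columns=["subject", "group", "timepoint", "value"])


class TestBonferroni:
    def test_definition_and_clamp(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0

    def test_matches_elementwise_oracle(self, rng):
        p = rng.uniform(0, 1, 20)
        m = 25
        expected = [min(1.0, m * v) for v in p]
        assert np.allclose(bonferroni(p, m), expected)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestOnewayRm:
    def test_null_numerator_gives_f_zero_p_one(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        res = rm_anova_oneway(long_table(x))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_matches_loop_oracle_on_100_random_designs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, 6))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            res = rm_anova_oneway(long_table(x))
            expected = oneway_rm_f_loop(x)
            assert res.F == pytest.approx(expected, rel=1e-8)
            assert (res.df_num, res.df_den) == (k - 1, (k - 1) * (n - 1))

    def test_two_conditions_equal_squared_paired_t(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, (6, 2))
            res = rm_anova_oneway(long_table(x))
            t_stat = sps.ttest_rel(x[:, 0], x[:, 1]).statistic
            assert res.F == pytest.approx(t_stat**2, rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(0, 2, (8, 4))
        table = long_table(x)
        res = rm_anova_oneway(table)
        ref = pg.rm_anova(data=table, dv="value", within="condition",
                          subject="subject")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        x = rng.normal(0, 1, (5, 3))
        base = rm_anova_oneway(long_table(x)).F
        assert rm_anova_oneway(long_table(x + 100.0)).F == pytest.approx(base, rel=1e-9)
        assert rm_anova_oneway(long_table(x * -3.7)).F == pytest.approx(base, rel=1e-9)

    def test_incomplete_design_rejected(self):
        table = long_table(np.zeros((3, 3))).iloc[:-1]
        with pytest.raises(DesignError, match="missing"):
            rm_anova_oneway(table)

    def test_posthoc_pairs_bonferroni_adjusted(self, rng):
        x = rng.normal(0, 1, (6, 3))
        res = rm_anova_oneway(long_table(x))
        assert len(res.posthoc) == 3
        for ph in res.posthoc:
            assert ph.p_adjusted == pytest.approx(min(1.0, 3 * ph.p_raw))


class TestMixedRm:
    def _random_design(self, rng, g=3, n=7, k=6):
        group_of = sum([[f"g{i}"] * n for i in range(g)], [])
        x = rng.normal(0, 1, (g * n, k)) + rng.normal(0, 1, (g * n, 1))
        return x, group_of

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            x, group_of = self._random_design(rng)
            results = {r.effect: r for r in rm_anova_mixed(mixed_long_table(x, group_of))}
            expected = mixed_f_loop(x, group_of)
            for effect, f_expected in expected.items():
                assert results[effect].F == pytest.approx(f_expected, rel=1e-8)
            assert results["group"].df_num == 2
            assert results["group"].df_den == 18
            assert results["time"].df_num == 5
            assert results["time"].df_den == 90

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x, group_of = self._random_design(rng)
        table = mixed_long_table(x, group_of)
        results = {r.effect: r for r in rm_anova_mixed(table)}
        ref = pg.mixed_anova(data=table, dv="value", within="timepoint",
                             between="group", subject="subject")
        ref = ref.set_index("Source")
        assert results["group"].F == pytest.approx(float(ref.loc["group", "F"]), rel=1e-9)
        assert results["time"].F == pytest.approx(
            float(ref.loc["timepoint", "F"]), rel=1e-9)
        assert results["group x time"].F == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-9)

    def test_null_case_f_near_zero(self, rng):
        medians = {"group": [], "time": [], "group x time": []}
        for _ in range(30):
            x = rng.normal(0, 1, (21, 6))
            group_of = ["a"] * 7 + ["b"] * 7 + ["c"] * 7
            for r in rm_anova_mixed(mixed_long_table(x, group_of)):
                medians[r.effect].append(r.F)
        for effect, fs in medians.items():
            assert np.median(fs) < 2.0

    def test_subject_in_two_groups_rejected(self, rng):
        table = mixed_long_table(rng.normal(0, 1, (4, 3)),
                                 ["a", "a", "b", "b"])
        table.loc[table["subject"] == "s0", "group"] = ["a", "b", "a"]
        with pytest.raises(DesignError, match="s0"):
            rm_anova_mixed(table)

    def test_posthoc_contrast_count(self, rng):
        x, group_of = self._random_design(rng, g=3, n=4, k=5)
        results = rm_anova_mixed(mixed_long_table(x, group_of))
        interaction = [r for r in results if r.effect == "group x time"][0]
        assert len(interaction.posthoc) == 3 * 5  # pairs x timepoints

    def test_type_one_error_calibrated(self, rng):
        # spherical Gaussian null: rejection rate per effect near alpha
        n_rep = 1000
        rejections = {"group": 0, "time": 0, "group x time": 0}
        group_of = ["a"] * 7 + ["b"] * 7 + ["c"] * 7
        for _ in range(n_rep):
            x = rng.normal(0, 1, (21, 6)) + rng.normal(0, 1, (21, 1))
            for r in rm_anova_mixed(mixed_long_table(x, group_of)):
                rejections[r.effect] += r.p < 0.05
        for effect, count in rejections.items():
            assert 0.03 <= count / n_rep <= 0.07, effect


class TestSignificanceReport:
    def test_strict_threshold(self):
        results = [
            AnovaResult("a", 5.0, 1, 10, 0.049),
            AnovaResult("b", 4.0, 1, 10, 0.05),
        ]
        report = significance_report(results, alpha=0.05)
        assert bool(report.loc[report["name"] == "a", "significant"].iloc[0])
        assert not bool(report.loc[report["name"] == "b", "significant"].iloc[0])

    def test_empty_input_gives_empty_report(self):
        assert significance_report([]).empty
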