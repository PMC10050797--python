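"""Trial comparison statistics: chi-square, ANOVA/Tukey, rank tests, Holm, OLS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from gwgbayes.stats import (
    ContingencyTable,
    covid_sensitivity,
    holm_adjust,
    kruskal_wallis,
    linear_regression_slope,
    one_way_anova,
    pearson_chi2,
    tukey_pairwise,
    wilcoxon_holm_pairwise,
    wilcoxon_rank_sum,
)


class TestPearsonChi2:
    def test_proportional_rows_give_zero(self):
        t = ContingencyTable.from_events([10, 20, 30], [30, 60, 90])
        res = pearson_chi2(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 10, 20, 30, 40
        t = ContingencyTable(
            np.array([[a, b], [c, d]]), ("g1", "g2"), ("yes", "no")
        )
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert pearson_chi2(t).statistic == pytest.approx(expected, abs=1e-10)

    def test_df2_p_equals_exp_minus_half_chi2(self):
        t = ContingencyTable.from_events([9, 25, 24], [34, 74, 70])
        res = pearson_chi2(t)
        assert res.df == 2
        assert res.p_value == pytest.approx(np.exp(-res.statistic / 2), rel=1e-12)

    def test_zero_marginal_raises(self):
        t = ContingencyTable(np.array([[0, 0], [3, 4]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError):
            pearson_chi2(t)

    def test_event_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_events([40], [34], groups=("CON",))

    def test_null_calibration(self):
        """Type-I error ~5% for 3x2 tables at the trial's group sizes."""
        rng = np.random.default_rng(0)
        sizes = np.array([34, 74, 70])
        n_rep, rate = 2000, 0.3
        rejections = 0
        for _ in range(n_rep):
            events = rng.binomial(sizes, rate)
            if events.sum() == 0 or (sizes - events).sum() == 0:
                continue  # degenerate column marginal, not testable
            t = ContingencyTable.from_events(events, sizes)
            rejections += pearson_chi2(t).p_value < 0.05
        frac = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(frac - 0.05) < 3 * se


class TestAnova:
    def test_hand_computed_example(self):
        values = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        labels = list("aaabbbccc")
        res = one_way_anova(values, labels)
        assert res.statistic == pytest.approx(3.0)
        assert res.p_value == pytest.approx(sps.f.sf(3.0, 2, 6))

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova(np.r_[x, y], ["a"] * 12 + ["b"] * 15)
        t, p = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=15)
        labels = np.array(list("aaaaabbbbbccccc"))
        base = one_way_anova(values, labels).statistic
        values2 = values.copy()
        values2[:5] = values[:5][::-1]
        assert one_way_anova(values2, labels).statistic == pytest.approx(base)

    @pytest.mark.parametrize(
        "values,labels",
        [
            ([1, 2, 3], ["a", "a", "a"]),
            ([1, 2, 3, 4], ["a", "a", "a", "b"]),
            ([1, 1, 2, 2], ["a", "a", "b", "b"]),
        ],
    )
    def test_errors(self, values, labels):
        with pytest.raises(ValueError):
            one_way_anova(values, labels)


class TestTukey:
    def test_identical_groups(self):
        res = tukey_pairwise([1, 2, 3] * 3, list("aaabbbccc"))
        assert np.allclose(res["difference"], 0.0)
        assert (res["p_adj"] > 0.95).all()

    def test_two_groups_matches_t_test(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        res = tukey_pairwise(np.r_[x, y], ["a"] * 10 + ["b"] * 10)
        _, p = sps.ttest_ind(x, y)
        assert res["p_adj"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=30)
        labels = np.repeat(list("abc"), 10)
        res = tukey_pairwise(values, labels)
        for _, row in res.iterrows():
            x = values[labels == row["group_a"]]
            y = values[labels == row["group_b"]]
            _, p_raw = sps.ttest_ind(x, y)
            assert row["p_adj"] >= p_raw - 1e-12


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert res.statistic == pytest.approx(4.5714, abs=1e-4)
        assert res.p_value == pytest.approx(np.exp(-res.statistic / 2), rel=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=12)
        labels = np.repeat(list("abc"), 4)
        base = kruskal_wallis(values, labels).statistic
        perm = rng.permutation(12)
        assert kruskal_wallis(values[perm], labels[perm]).statistic == pytest.approx(base)

    def test_all_identical_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])

    def test_chi2_approximation_close_to_exact_permutation(self):
        """Groups of (2,2,2): compare with the full 90-permutation null."""
        values = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        observed = kruskal_wallis(values, labels)

        def h_stat(vals):
            ranks = sps.rankdata(vals)
            r = [ranks[:2].sum(), ranks[2:4].sum(), ranks[4:].sum()]
            return 12 / (6 * 7) * sum(ri**2 / 2 for ri in r) - 3 * 7

        stats_null = []
        for perm in itertools.permutations(range(6)):
            stats_null.append(h_stat(values[list(perm)]))
        stats_null = np.array(stats_null)
        exact_p = np.mean(stats_null >= observed.statistic - 1e-9)
        assert abs(observed.p_value - exact_p) < 0.15


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.123])[0] == pytest.approx(0.123)

    def test_hand_computed_stepdown(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=9)
        _, adj_sm, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), adj_sm)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bounds_and_order_equivariance(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.argsort(p)
        adj_perm = holm_adjust(np.asarray(p)[perm])
        assert np.allclose(adj_perm, adj[perm])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_3v3(self):
        """All C(6,3)=20 assignments enumerated by brute force."""
        x = np.array([1.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 9.0])
        res = wilcoxon_rank_sum(x, y)
        pooled = np.r_[x, y]
        ranks = sps.rankdata(pooled)
        obs_r1 = ranks[:3].sum()
        mean_r1 = 3 * 7 / 2
        null = []
        for idx in itertools.combinations(range(6), 3):
            null.append(ranks[list(idx)].sum())
        null = np.array(null)
        exact_p = np.mean(np.abs(null - mean_r1) >= abs(obs_r1 - mean_r1) - 1e-9)
        assert res.p_value == pytest.approx(exact_p, abs=1e-12)

    def test_pairwise_holm_composition(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=24)
        labels = np.repeat(list("abc"), 8)
        table = wilcoxon_holm_pairwise(values, labels)
        assert np.allclose(
            table["p_holm"], holm_adjust(table["p_raw"].to_numpy())
        )
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])


class TestLinearRegression:
    def test_constant_y(self):
        res = linear_regression_slope(np.arange(10.0), np.ones(10))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = linear_regression_slope(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.ci_low == res.ci_high == pytest.approx(2.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        res = linear_regression_slope(x, y)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        assert res.slope == pytest.approx(sxy / sxx, abs=1e-10)

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            linear_regression_slope(np.ones(5), np.arange(5.0))


def test_covid_sensitivity_recovers_shift():
    rng = np.random.default_rng(9)
    labels = np.repeat(["CON", "EXE"], 40)
    covid = np.tile([0, 1], 40)
    gwg = 15 + 3.0 * covid * (labels == "EXE") + rng.normal(0, 0.5, 80)
    tab = covid_sensitivity(gwg, covid, labels).set_index("group")
    assert tab.loc["EXE", "difference"] == pytest.approx(3.0, abs=0.5)
    assert tab.loc["CON", "difference"] == pytest.approx(0.0, abs=0.5)
    assert tab.loc["EXE", "p_value"] < 0.001
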