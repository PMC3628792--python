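"""Rank test, two-way ANOVA, fold change, BH correction, and list combination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircascade.diffexpr import (
    SelectionCriteria,
    bh_adjust,
    combine_lists,
    fold_change,
    mann_whitney_u,
    select_de_genes,
    two_way_anova,
)
from mircascade.expression import percentile_shift_normalize
from mircascade.synthetic_data import SimConfig, generate_expression


def exact_mw_p(a, b):
    """Two-sided exact Mann–Whitney p by full enumeration of label assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(b) / 2

    def u_of(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    obs = abs(u_of(range(n1)) - mu)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= obs - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_identical_groups(self):
        U, p, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert U == pytest.approx(4.5)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_groups_exact(self):
        U, p, method = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert method == "exact"
        assert U == 0
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (4, 4), (5, 5), (5, 4)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2) + 0.5
        _, p, method = mann_whitney_u(a, b)
        assert method == "exact"
        assert p == pytest.approx(exact_mw_p(a, b))

    def test_ties_fall_back_to_asymptotic(self):
        _, _, method = mann_whitney_u([1, 1, 2], [2, 3, 4])
        assert method == "asymptotic"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            mann_whitney_u([1], [2, 3])


class TestTwoWayAnova:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(0)
        fa = np.repeat(["a1", "a2"], 6)
        fb = np.tile(np.repeat(["b1", "b2"], 3), 2)
        y = rng.normal(size=12) + (fa == "a2") * 1.0
        res = two_way_anova(y, fa, fb, factor_names=("A", "B"))
        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        table = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
        assert res["A"][0][0] == pytest.approx(table.loc["C(A)", "F"])
        assert res["A"][1][0] == pytest.approx(table.loc["C(A)", "PR(>F)"])
        assert res["B"][0][0] == pytest.approx(table.loc["C(B)", "F"])
        assert res["interaction"][1][0] == pytest.approx(
            table.loc["C(A):C(B)", "PR(>F)"]
        )

    def test_noiseless_planted_strain_effect(self):
        fa = np.repeat(["a1", "a2"], 4)
        fb = np.tile(["b1", "b1", "b2", "b2"], 2)
        y = (fa == "a2") * 1.0  # pure factor-A effect, zero noise
        res = two_way_anova(y, fa, fb)
        assert res["A"][1][0] == 0.0  # guarded as p ~ 0 for infinite F
        assert res["B"][1][0] == 1.0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(42)
        fa = np.repeat(["a1", "a2"], 6)
        fb = np.tile(np.repeat(["b1", "b2"], 3), 2)
        X = rng.normal(size=(2000, 12))
        _, p = two_way_anova(X, fa, fb)["A"]
        stat, ks_p = stats.kstest(p, "uniform")
        assert ks_p > 0.01

    def test_unreplicated_additive_model(self):
        fa = np.repeat(["a1", "a2", "a3"], 2)
        fb = np.tile(["b1", "b2"], 3)
        y = np.array([1.0, 2.0, 1.5, 2.6, 0.9, 2.1])
        res = two_way_anova(y, fa, fb, replicated=False)
        assert set(res) == {"A", "B"}
        assert np.isfinite(res["A"][1][0])

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova(
                np.ones(4), ["a1", "a1", "a1", "a2"], ["b1", "b2", "b1", "b1"]
            )


class TestFoldChange:
    @pytest.fixture()
    def matrix(self):
        from tests.test_expression import make_matrix

        rng = np.random.default_rng(3)
        return make_matrix(rng.normal(3, 1, size=(10, 6)), scale="log2")

    def test_equal_means_fail_threshold(self, matrix):
        m = matrix
        m.values.iloc[0, :] = 3.0
        fc = fold_change(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert fc["fold_change"].iloc[0] == pytest.approx(1.0)
        assert fc["fold_change"].iloc[0] < 1.5

    def test_one_log2_unit_doubles(self, matrix):
        m = matrix
        m.values.iloc[1, :3] = 4.0
        m.values.iloc[1, 3:] = 3.0
        fc = fold_change(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert fc["ratio"].iloc[1] == pytest.approx(2.0)
        assert fc["direction"].iloc[1] == 1

    def test_matches_antilog_mean_oracle(self, matrix):
        g1, g2 = ["s0", "s2"], ["s1", "s3", "s5"]
        fc = fold_change(matrix, g1, g2)
        vals = matrix.values
        expected = 2.0 ** (vals[g1].mean(axis=1) - vals[g2].mean(axis=1))
        np.testing.assert_allclose(fc["ratio"], expected)
        np.testing.assert_allclose(
            fc["fold_change"], np.maximum(expected, 1 / expected)
        )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_three_increasing(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_direct_min_over_tail_formula(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            j = m - rank_from_end  # 1-based rank in sorted order
            running = min(running, m * p[idx] / j)
            expected[idx] = running
        np.testing.assert_allclose(adj, expected)

    @pytest.mark.parametrize("q", [0.01, 0.05, 0.2])
    def test_rejections_match_step_up_rule(self, q):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(size=80), rng.uniform(0, 1e-3, size=20)])
        adj = bh_adjust(p)
        m = len(p)
        ps = np.sort(p)
        passing = np.where(ps <= (np.arange(1, m + 1) / m) * q)[0]
        k = passing.max() + 1 if len(passing) else 0
        step_up_rejects = set(np.argsort(p)[:k])
        assert set(np.where(adj <= q)[0]) == step_up_rejects

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.2])


class TestSelection:
    def test_planted_strain_genes_have_rank_test_power_with_six_replicates(self):
        # At 6 arrays per group the exact rank test can reach p = 2/924, so
        # BH-corrected selection of strongly planted genes is possible.
        config = SimConfig(n_genes=400, n_replicates_per_condition=6, seed=11)
        expr, truth = generate_expression(config)
        norm, _ = percentile_shift_normalize(expr)
        sel = select_de_genes(norm)
        planted = set(truth.strain_de)
        recovered = len(planted & sel.lists["list1"]) / len(planted)
        assert recovered >= 0.8

    def test_infinite_fc_threshold_empties_fc_lists(self):
        config = SimConfig(n_genes=100, seed=1)
        expr, _ = generate_expression(config)
        norm, _ = percentile_shift_normalize(expr)
        crit = SelectionCriteria(fc_threshold=1e9)
        sel = select_de_genes(norm, criteria1=crit, criteria2=crit)
        assert sel.lists["list1"] == set()
        assert sel.lists["list2"] == set()

    def test_relaxing_thresholds_never_shrinks_lists(self):
        config = SimConfig(n_genes=300, seed=2)
        expr, _ = generate_expression(config)
        norm, _ = percentile_shift_normalize(expr)
        tight = select_de_genes(
            norm,
            criteria1=SelectionCriteria(fc_threshold=2.0, p_threshold=0.01),
            criteria2=SelectionCriteria(fc_threshold=2.0),
            criteria3=SelectionCriteria(test="anova", p_threshold=0.01),
        )
        loose = select_de_genes(
            norm,
            criteria1=SelectionCriteria(fc_threshold=1.2, p_threshold=0.5),
            criteria2=SelectionCriteria(fc_threshold=1.2),
            criteria3=SelectionCriteria(test="anova", p_threshold=0.5),
        )
        for name in ("list1", "list2", "list3"):
            assert tight.lists[name] <= loose.lists[name]


class TestCombineLists:
    def test_identical_sets(self):
        a = {"x", "y"}
        both = combine_lists(a, a, a, rule="shared_by_2_of_3")
        union = combine_lists(a, a, a, rule="union_all")
        assert both.combined_set == union.combined_set == a
        assert both.region_counts["111"] == 2

    def test_chain_example(self):
        venn2 = combine_lists({"1", "2"}, {"2", "3"}, {"3", "4"}, "shared_by_2_of_3")
        assert venn2.combined_set == {"2", "3"}
        venn_u = combine_lists({"1", "2"}, {"2", "3"}, {"3", "4"}, "union_all")
        assert venn_u.combined_set == {"1", "2", "3", "4"}
        assert sum(venn_u.region_counts.values()) == 4

    def test_disjoint_sets(self):
        venn = combine_lists({"a"}, {"b"}, {"c"}, "shared_by_2_of_3")
        assert venn.combined_set == set()
        assert venn.region_counts == {
            "100": 1, "010": 1, "001": 1, "110": 0, "101": 0, "011": 0, "111": 0,
        }
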