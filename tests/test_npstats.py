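import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from retinatune.npstats import (
    HVTable,
    adjust_pvalues,
    compare_algorithms,
    friedman,
    kruskal_wallis,
    mann_whitney_u,
)

# Unadjusted pairwise p-values printed in the source comparison study
TABLE3_UNADJUSTED = [
    0.0963, 0.0015, 0.0002, 0.0233, 0.0003, 0.0002, 0.4497, 0.0002, 0.0002, 0.0002,
]


class TestKruskalWallis:
    def test_hand_computed_value(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.8571, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1, 12) for loc in (0.0, 0.4, 1.0)]
        h, p = kruskal_wallis(groups)
        h_sp, p_sp = sps.kruskal(*groups)
        assert h == pytest.approx(h_sp)
        assert p == pytest.approx(p_sp)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.0, 7.0], [3.0, 5.0, 11.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2)

    def test_identical_groups_near_zero(self):
        h, p = kruskal_wallis([[1, 3, 5, 7], [1, 3, 5, 7]])
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_all_identical_values_convention(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert p == 1.0

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestFriedman:
    def test_perfect_ranking_maximal(self):
        # every block ranks the 3 treatments identically -> chi2 = n(k-1) = 20
        m = np.tile([1.0, 2.0, 3.0], (10, 1))
        chi2, p = friedman(m)
        assert chi2 == pytest.approx(20.0)

    def test_constant_matrix_zero(self):
        chi2, _ = friedman(np.full((6, 4), 3.3))
        assert chi2 == pytest.approx(0.0)

    def test_block_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (8, 4))
        chi2, _ = friedman(m)
        chi2_p, _ = friedman(m[rng.permutation(8)])
        assert chi2 == pytest.approx(chi2_p)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, (12, 4))
        chi2, p = friedman(m)
        chi2_sp, p_sp = sps.friedmanchisquare(*[m[:, j] for j in range(4)])
        assert chi2 == pytest.approx(chi2_sp)
        assert p == pytest.approx(p_sp)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman(np.zeros((1, 4)))


class TestMannWhitneyU:
    def test_complete_separation_ten_vs_ten(self):
        x = np.arange(1.0, 11.0)
        y = np.arange(11.0, 21.0)
        u, p = mann_whitney_u(x, y, continuity=False)
        # z = 50 / sqrt(175); two-sided normal tail
        assert p == pytest.approx(0.000157, abs=2e-6)
        assert round(p, 4) == 0.0002

    def test_u_sum_identity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 13)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_symmetric_p(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 9)
        _, pxy = mann_whitney_u(x, y)
        _, pyx = mann_whitney_u(y, x)
        assert pxy == pytest.approx(pyx)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        u, p = mann_whitney_u(x, y, continuity=False)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAdjustPvalues:
    def test_bonferroni_m20_table_entries(self):
        adj = adjust_pvalues(TABLE3_UNADJUSTED, "bonferroni", m=20)
        lookup = dict(zip(TABLE3_UNADJUSTED, adj))
        assert round(lookup[0.0015], 4) == 0.0300
        assert round(lookup[0.0963], 4) == 1.0000

    def test_step_up_m10_table_entries(self):
        adj = adjust_pvalues(TABLE3_UNADJUSTED, "step_up_bh", m=10)
        lookup = dict(zip(TABLE3_UNADJUSTED, adj))
        assert round(lookup[0.0963], 4) == 0.1070
        assert round(lookup[0.0015], 4) == 0.0021
        assert round(lookup[0.0003], 4) == 0.0005
        assert round(lookup[0.0002], 4) == 0.0004

    @pytest.mark.parametrize("method", ["bonferroni", "hochberg", "hommel", "step_up_bh"])
    def test_single_p_identity(self, method):
        assert adjust_pvalues([0.042], method)[0] == pytest.approx(0.042)

    @pytest.mark.parametrize("method,sm_name", [
        ("hochberg", "simes-hochberg"),
        ("hommel", "hommel"),
        ("bonferroni", "bonferroni"),
        ("step_up_bh", "fdr_bh"),
    ])
    def test_matches_statsmodels(self, method, sm_name):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(2, 12)))
            mine = adjust_pvalues(p, method)
            _, theirs, _, _ = multipletests(p, method=sm_name)
            assert np.allclose(mine, theirs)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_at_least_unadjusted_and_capped(self, pvals):
        p = np.array(pvals)
        for method in ("bonferroni", "hochberg", "hommel", "step_up_bh"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_dominance_ordering(self, pvals):
        # hommel <= hochberg <= bonferroni elementwise at m = len(pvals)
        p = np.array(pvals)
        hommel = adjust_pvalues(p, "hommel")
        hochberg = adjust_pvalues(p, "hochberg")
        bonf = adjust_pvalues(p, "bonferroni")
        assert np.all(hommel <= hochberg + 1e-12)
        assert np.all(hochberg <= bonf + 1e-12)

    def test_bonferroni_idempotent_on_capped(self):
        p = [0.2, 0.9, 1.0]
        once = adjust_pvalues(p, "bonferroni", m=3)
        twice = adjust_pvalues(np.minimum(once, 1.0).tolist(), "bonferroni", m=3)
        assert np.all(twice >= once)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "bonferroni")

    def test_hommel_custom_multiplier_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2], "hommel", m=5)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "sidak")


class TestCompareAlgorithms:
    def _table(self, columns, labels):
        return HVTable(np.column_stack(columns), tuple(labels))

    def test_pair_count(self):
        rng = np.random.default_rng(7)
        cols = [rng.normal(i, 1, 10) for i in range(5)]
        report = compare_algorithms(self._table(cols, "abcde"))
        assert len(report.pairwise_p) == 10

    def test_identical_columns_convention(self):
        col = np.full(6, 2.5)
        report = compare_algorithms(self._table([col, col, col], "abc"))
        assert report.kruskal_p == 1.0
        assert report.friedman_p == 1.0
        for flags in report.significant.values():
            assert not any(flags.values())

    def test_separated_columns_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        report = compare_algorithms(self._table([a, b], "ab"))
        assert all(p < 0.001 for p in report.pairwise_p.values())

    def test_box_summary_per_algorithm(self):
        rng = np.random.default_rng(9)
        cols = [rng.normal(i, 1, 8) for i in range(3)]
        report = compare_algorithms(self._table(cols, "abc"))
        assert set(report.box_summary) == set("abc")
        for stats in report.box_summary.values():
            assert stats["min"] <= stats["q1"] <= stats["median"] <= stats["q3"] <= stats["max"]

    def test_custom_multipliers(self):
        rng = np.random.default_rng(10)
        cols = [rng.normal(i, 1, 10) for i in range(5)]
        report = compare_algorithms(
            self._table(cols, "abcde"),
            adjust_methods={"bonferroni": 20, "step_up_bh": 10},
        )
        assert set(report.adjusted) == {"bonferroni", "step_up_bh"}

    def test_table_validation(self):
        with pytest.raises(ValueError):
            HVTable(np.zeros((1, 3)), ("a", "b", "c"))
        with pytest.raises(ValueError):
            HVTable(np.full((3, 2), np.nan), ("a", "b"))
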