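"""Test selection rules, exact tests, corrections, and count contrasts."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossri import stats as cstats
from crossri.stats import (bonferroni, compare_counts, compare_sperm,
                           count_tables_with_margins, fisher_exact_rc,
                           permutation_two_group, run_binary_comparison,
                           select_binary_test)


def fisher_2x2_oracle(table) -> float:
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = comb(n, c1)
    probs = [Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
             for k in range(max(0, c1 - r2), min(r1, c1) + 1)]
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    return float(sum(p for p in probs if p <= p_obs))


class TestSelection:
    @pytest.mark.parametrize("table,expected", [
        ([[21, 0], [19, 21]], "fisher_exact"),   # zero cell
        ([[10, 10], [10, 10]], "chi_squared"),
        ([[6, 6], [6, 5]], "fisher_exact"),      # boundary: a cell of 5
        ([[6, 6], [6, 6]], "chi_squared"),       # all cells exceed 5
    ])
    def test_rule(self, table, expected):
        assert select_binary_test(table) == expected

    def test_invariant_to_permutation(self):
        table = np.array([[2, 30], [8, 12]])
        base = select_binary_test(table)
        assert select_binary_test(table[::-1]) == base
        assert select_binary_test(table[:, ::-1]) == base
        assert select_binary_test(table.T) == base

    @pytest.mark.parametrize("bad", [[[0, 0], [0, 0]], [[1, -1], [2, 3]],
                                     [[]]])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            select_binary_test(bad)


class TestFisherExact:
    @pytest.mark.parametrize("table", [
        [[1, 9], [11, 3]], [[5, 5], [5, 5]], [[21, 0], [19, 21]],
        [[2, 7], [8, 2]], [[0, 12], [12, 0]], [[3, 3], [4, 4]],
    ])
    def test_2x2_matches_rational_enumeration(self, table):
        mine = fisher_exact_rc(table).p_value
        assert mine == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)

    def test_2x2_known_values(self):
        assert fisher_exact_rc([[1, 9], [11, 3]]).p_value == pytest.approx(
            0.00275946, abs=1e-7)
        assert fisher_exact_rc([[5, 5], [5, 5]]).p_value == pytest.approx(
            1.0, abs=1e-12)
        assert fisher_exact_rc([[21, 0], [19, 21]]).p_value < 0.001

    def test_rxc_enumeration_matches_r_reference(self):
        # R: fisher.test(matrix(c(3,1,4,2,5,1,1,2,3), nrow=3, byrow=TRUE))
        res = fisher_exact_rc([[3, 1, 4], [2, 5, 1], [1, 2, 3]])
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(0.3190094, abs=1e-6)

    def test_monte_carlo_converges_to_exact(self):
        table = [[3, 1, 4], [2, 5, 1], [1, 2, 3]]
        exact = fisher_exact_rc(table).p_value
        errs = []
        for n_sim in (500, 20_000):
            mc = fisher_exact_rc(table, max_tables=1, n_sim=n_sim, seed=3)
            assert mc.method == "monte_carlo"
            assert abs(mc.p_value - exact) < 4 * mc.se + 1e-3
            errs.append(abs(mc.p_value - exact))
        assert errs[1] < errs[0]

    def test_table_count_oracle(self):
        # 2x2 with margins (r1, r2), (c1, c2): free cell ranges over
        # max(0, c1-r2)..min(r1, c1)
        assert count_tables_with_margins([5, 5], [5, 5]) == 6
        assert count_tables_with_margins([1, 1], [1, 1]) == 2


class TestBonferroni:
    @pytest.mark.parametrize("ps,expected", [
        ([0.01, 0.04], [0.02, 0.08]),
        ([0.5], [0.5]),
        ([0.3, 0.6, 0.9], [0.9, 1.0, 1.0]),
    ])
    def test_known_values(self, ps, expected):
        assert bonferroni(ps) == pytest.approx(expected)

    def test_explicit_family_size(self):
        assert bonferroni([0.01], family_size=6) == pytest.approx([0.06])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=10))
    @settings(derandomize=True, max_examples=100)
    def test_adjusted_never_below_raw(self, ps):
        adj = bonferroni(ps)
        assert all(0 <= a <= 1 and a >= p - 1e-12
                   for a, p in zip(adj, ps))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        ps = [0.001, 0.02, 0.2, 0.9]
        ref = multipletests(ps, method="bonferroni")[1]
        assert bonferroni(ps) == pytest.approx(list(ref))


class TestBinaryPipeline:
    def test_null_rejection_rate_within_nominal(self):
        """Type-I error of selection rule + test under a binomial null."""
        rng = np.random.default_rng(42)
        n_data, n, p = 1000, 15, 0.5
        rejections = 0
        for _ in range(n_data):
            k1, k2 = rng.binomial(n, p, 2)
            table = [[k1, n - k1], [k2, n - k2]]
            res = run_binary_comparison(table)
            rejections += res.p_value < 0.05
        rate = rejections / n_data
        se = math.sqrt(0.05 * 0.95 / n_data)
        assert rate <= 0.05 + 2 * se


class TestCompareCounts:
    def test_identical_groups_give_zero_contrast(self):
        groups = {"a": [7, 7, 7, 7], "b": [7, 7, 7, 7]}
        res = compare_counts(groups, engine="permutation", n_perm=200)
        assert res[0].estimate == 0.0
        assert res[0].p_adjusted == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        groups = {"lo": rng.poisson(10, 30), "hi": rng.poisson(30, 30)}
        res = compare_counts(groups, engine="permutation", n_perm=2000,
                             seed=1)
        assert res[0].significant

    def test_glm_and_permutation_agree_on_strong_effect(self):
        rng = np.random.default_rng(2)
        groups = {"lo": rng.poisson(10, 30), "hi": rng.poisson(30, 30),
                  "mid": rng.poisson(20, 30)}
        perm = {r.groups: r.significant
                for r in compare_counts(groups, engine="permutation",
                                        n_perm=2000, seed=2)}
        glm = {r.groups: r.significant
               for r in compare_counts(groups, family="quasipoisson",
                                       engine="glm")}
        assert perm == glm

    def test_type_one_error_of_auto_engine(self):
        """Same-distribution groups stay non-significant ~95% of the time."""
        rng = np.random.default_rng(7)
        n_data, false_pos = 400, 0
        for _ in range(n_data):
            groups = {"a": rng.normal(50, 8, 50), "b": rng.normal(50, 8, 50)}
            res = compare_counts(groups, engine="auto", n_perm=400,
                                 seed=int(rng.integers(2**31)))
            false_pos += any(r.significant for r in res)
        rate = false_pos / n_data
        se = math.sqrt(0.05 * 0.95 / n_data)
        assert rate <= 0.06 + 2 * se

    def test_zero_variance_zero_mean_contrast_flagged(self):
        res = compare_counts({"a": [0, 0, 0], "b": [0, 0, 0]},
                             engine="permutation", n_perm=100)
        assert math.isnan(res[0].p_value)
        assert "undefined" in res[0].extra

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_counts({"a": [1, 2, 3]})


class TestCompareSperm:
    def test_identical_samples_not_significant(self):
        a = [100.0, 120.0, 140.0, 160.0, 180.0]
        res = compare_sperm(a, a)
        assert res.p_value > 0.9

    def test_welch_selected_for_normal_unequal_variance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(2000, 100, 40)
        b = rng.normal(2000, 400, 40)
        assert compare_sperm(a, b).test_name == "welch_t"

    def test_wilcoxon_selected_for_skewed_data_and_detects_shift(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(6, 0.8, 100))
        b = 1.4 * np.exp(rng.normal(6, 0.8, 100))  # 40% shift
        res = compare_sperm(a, b)
        assert res.test_name == "wilcoxon_rank_sum"
        assert res.significant

    def test_reports_medians_and_quartiles(self):
        a = [100.0, 200.0, 300.0, 400.0]
        b = [150.0, 250.0, 350.0, 450.0]
        res = compare_sperm(a, b)
        assert res.extra["median"] == (250.0, 300.0)
        assert res.extra["n"] == (4, 4)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_sperm([1.0, 2.0], [1.0, 2.0, 3.0])


class TestResultInvariants:
    def test_adjusted_below_raw_rejected(self):
        with pytest.raises(ValueError):
            cstats.TestResult("t", 1.0, p_value=0.5, p_adjusted=0.2)

    def test_significance_uses_adjusted_p(self):
        res = cstats.TestResult("t", 1.0, p_value=0.01, p_adjusted=0.2)
        assert not res.significant
        assert cstats.TestResult("t", 1.0, p_value=0.01).significant
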