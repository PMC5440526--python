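"""The small-sample test battery against oracles and scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from micromiss import smallstats as ss
from micromiss.smallstats import Contingency2x2

tables_strategy = st.tuples(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
).filter(lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0)


class TestChi2:
    def test_published_ut_table(self):
        res = ss.chi2_uncorrected(Contingency2x2.from_proportions(151, 335, 185, 281))
        assert res.p_value == pytest.approx(2.544e-7, rel=1e-3)

    def test_published_proteobacteria_table(self):
        res = ss.chi2_uncorrected(Contingency2x2.from_proportions(56, 335, 25, 281))
        assert res.p_value == pytest.approx(0.00423, rel=1e-2)

    def test_equal_proportions(self):
        res = ss.chi2_uncorrected((5, 5, 5, 5))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_column_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = ss.chi2_uncorrected((0, 10, 0, 5))
        assert res.p_value == 1.0

    @given(tables_strategy)
    def test_statistic_equals_squared_pooled_z(self, table):
        a, b, c, d = table
        if a + c == 0 or b + d == 0:
            return
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        pp = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        res = ss.chi2_uncorrected(table)
        assert res.statistic == pytest.approx(z * z, abs=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 40, size=4)
            ours = ss.chi2_uncorrected((a, b, c, d))
            chi2, p, _, _ = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False
            )
            assert ours.statistic == pytest.approx(chi2)
            assert ours.p_value == pytest.approx(p)


def fisher_bruteforce(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins and
    sum factorial-formula point probabilities <= the observed one."""
    n1, col1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (
            math.comb(n1, x) * math.comb(n - n1, col1 - x) / math.comb(n, col1)
        )

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, col1 - (n - n1)), min(n1, col1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_zero_margin_p_one(self):
        assert ss.fisher_exact_two_tailed((0, 10, 0, 5)).p_value == 1.0

    def test_seven_vs_zero(self):
        res = ss.fisher_exact_two_tailed((7, 3, 0, 5))
        assert res.p_value == pytest.approx(0.02564, abs=1e-4)

    def test_published_verrucomicrobia(self):
        assert ss.fisher_exact_two_tailed((1, 588, 1, 485)).p_value > 0.99

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            ours = ss.fisher_exact_two_tailed((a, b, c, d)).p_value
            assert ours == pytest.approx(fisher_bruteforce(a, b, c, d), abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            ours = ss.fisher_exact_two_tailed((a, b, c, d)).p_value
            theirs = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_doubling_method_option(self):
        # doubling the smaller tail reproduces the legacy-style value
        res = ss.fisher_exact_two_tailed((3, 332, 0, 281), method="doubling")
        assert res.p_value == pytest.approx(0.32, abs=0.02)


def barnard_bruteforce(a, b, c, d, grid=500):
    """Direct double-loop oracle for the pooled-Wald unconditional test."""
    n1, n2 = a + b, c + d

    def t_stat(x1, x2):
        pp = (x1 + x2) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
        if var <= 0:
            return 0.0
        return (x1 / n1 - x2 / n2) / math.sqrt(var)

    t_obs = abs(t_stat(a, c))
    region = [
        (x1, x2)
        for x1 in range(n1 + 1)
        for x2 in range(n2 + 1)
        if abs(t_stat(x1, x2)) >= t_obs - 1e-12
    ]
    best = 0.0
    for pi in np.linspace(1e-6, 1 - 1e-6, grid):
        total = sum(
            stats.binom.pmf(x1, n1, pi) * stats.binom.pmf(x2, n2, pi)
            for x1, x2 in region
        )
        best = max(best, total)
    return best


class TestBarnard:
    def test_published_gallolyticus_table(self):
        res = ss.barnard_exact_two_tailed((7, 3, 0, 5))
        assert res.p_value == pytest.approx(0.0147, abs=0.0005)

    def test_published_peroris_table(self):
        res = ss.barnard_exact_two_tailed((9, 1, 1, 4))
        assert res.p_value == pytest.approx(0.0093, abs=0.0005)

    def test_null_table_p_one(self):
        res = ss.barnard_exact_two_tailed((2, 2, 2, 2))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ss.barnard_exact_two_tailed((2, 2, 2, 2), n_grid=5)

    def test_statistic_is_pooled_z(self):
        res = ss.barnard_exact_two_tailed((7, 3, 0, 5))
        chi = ss.chi2_uncorrected((7, 3, 0, 5)).statistic
        assert res.statistic**2 == pytest.approx(chi, abs=1e-10)

    def test_matches_bruteforce_oracle(self):
        for table in [(3, 2, 0, 4), (5, 1, 1, 3), (4, 4, 2, 2), (6, 0, 2, 3)]:
            ours = ss.barnard_exact_two_tailed(table, n_grid=500, refine=False).p_value
            assert ours == pytest.approx(barnard_bruteforce(*table), abs=1e-9)

    @pytest.mark.parametrize("table", [(7, 3, 0, 5), (9, 1, 1, 4), (5, 2, 1, 3)])
    def test_matches_scipy(self, table):
        # scipy.stats.barnard_exact treats COLUMNS as the two binomial
        # samples, so the independent cross-check transposes our
        # rows-are-groups layout
        a, b, c, d = table
        res = ss.barnard_exact_two_tailed(table)
        ref = stats.barnard_exact([[a, c], [b, d]], pooled=True)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-7)

    def test_never_below_scipy(self, rng):
        # exact |T| ties (every table's mirror) are always kept in our
        # rejection region, so the maximized tail probability can only be
        # >= scipy's, which drops ties that float rounding orders below
        for _ in range(10):
            a, c = (int(v) for v in rng.integers(0, 6, size=2))
            b, d = (int(v) for v in rng.integers(1, 6, size=2))
            ours = ss.barnard_exact_two_tailed((a, b, c, d)).p_value
            ref = stats.barnard_exact([[a, c], [b, d]], pooled=True).pvalue
            assert ours >= ref - 1e-9

    def test_unpooled_variant_available(self):
        res = ss.barnard_exact_two_tailed((9, 1, 1, 4), statistic="wald_unpooled")
        assert res.p_value == pytest.approx(0.0269, abs=0.002)


class TestPooledT:
    def test_published_new_species_comparison(self):
        res = ss.pooled_t_two_tailed(1.8, 1.5, 10, 5.0, 2.6, 5)
        assert res.p_value == pytest.approx(0.00907, abs=5e-4)
        assert res.df == 13

    def test_published_shannon_comparison(self):
        res = ss.pooled_t_two_tailed(3.2, 0.8, 10, 3.8, 0.8, 5)
        assert res.p_value == pytest.approx(0.194, abs=5e-3)

    def test_equal_means_p_one(self):
        res = ss.pooled_t_two_tailed(2.0, 1.0, 5, 2.0, 2.0, 5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_vectors_equal_summaries(self, rng):
        x = rng.normal(0, 1, size=8)
        y = rng.normal(1, 2, size=6)
        from_vec = ss.pooled_t_from_vectors(x, y)
        from_sum = ss.pooled_t_two_tailed(
            x.mean(), x.std(ddof=1), 8, y.mean(), y.std(ddof=1), 6
        )
        assert from_vec.p_value == pytest.approx(from_sum.p_value)

    def test_degenerate_zero_variance(self):
        assert ss.pooled_t_two_tailed(1, 0, 5, 1, 0, 5).p_value == 1.0
        with pytest.warns(UserWarning):
            assert ss.pooled_t_two_tailed(1, 0, 5, 2, 0, 5).p_value == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ss.pooled_t_two_tailed(1, 1, 1, 2, 1, 5)


def mw_enumeration_oracle(x, y):
    """Enumerate every relabelling of the pooled values (multiset splits)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return hits / total


class TestMannWhitney:
    def test_identical_split_p_one(self):
        assert ss.mann_whitney_two_tailed([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_three_vs_three_matches_20_split_enumeration(self):
        x, y = [1.0, 5.0, 9.0], [2.0, 3.0, 4.0]
        res = ss.mann_whitney_two_tailed(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(mw_enumeration_oracle(x, y))

    def test_exact_with_ties_matches_enumeration(self):
        x, y = [1.0, 2.0, 2.0, 7.0], [2.0, 5.0, 6.0]
        res = ss.mann_whitney_two_tailed(x, y)
        assert res.p_value == pytest.approx(mw_enumeration_oracle(x, y))

    def test_exact_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        res = ss.mann_whitney_two_tailed(x, y, method="exact")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_asymptotic_agree_moderate_n(self, rng):
        x = rng.normal(0, 1, size=6)
        y = rng.normal(0.5, 1, size=6)
        exact = ss.mann_whitney_two_tailed(x, y, method="exact").p_value
        approx = ss.mann_whitney_two_tailed(x, y, method="asymptotic").p_value
        assert abs(exact - approx) < 0.01

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ss.mann_whitney_two_tailed([], [1.0])


class TestOneSampleProportion:
    def test_at_null_p_one(self):
        assert ss.one_sample_proportion_normal(50, 100, 0.5).p_value == 1.0

    def test_closed_form(self):
        res = ss.one_sample_proportion_normal(90, 100, 0.5)
        assert res.statistic == pytest.approx(8.0)
        assert res.p_value == pytest.approx(2 * stats.norm.cdf(-8.0))

    @pytest.mark.parametrize("k,n,p0", [(1, 0, 0.5), (5, 3, 0.5), (1, 5, 0.0)])
    def test_invalid_inputs(self, k, n, p0):
        with pytest.raises(ValueError):
            ss.one_sample_proportion_normal(k, n, p0)


class TestGroupSwapSymmetry:
    @given(tables_strategy)
    def test_two_tailed_tests_invariant_under_group_swap(self, table):
        t = Contingency2x2(*table)
        swapped = t.swapped()
        assert ss.fisher_exact_two_tailed(t).p_value == pytest.approx(
            ss.fisher_exact_two_tailed(swapped).p_value, abs=1e-12
        )
        if t.a + t.c > 0 and t.b + t.d > 0:
            assert ss.chi2_uncorrected(t).p_value == pytest.approx(
                ss.chi2_uncorrected(swapped).p_value, abs=1e-12
            )

    def test_barnard_invariant_under_group_swap(self):
        for table in [(7, 3, 0, 5), (4, 2, 1, 3), (2, 5, 3, 1)]:
            t = Contingency2x2(*table)
            assert ss.barnard_exact_two_tailed(t).p_value == pytest.approx(
                ss.barnard_exact_two_tailed(t.swapped()).p_value, abs=1e-9
            )


class TestAutoSelection:
    def test_small_per_sample_tables_get_barnard(self):
        assert ss.choose_two_proportion_test((7, 3, 0, 5), per_sample=True) == "barnard"

    def test_small_expected_cells_get_fisher(self):
        assert ss.choose_two_proportion_test((1, 588, 1, 485)) == "fisher"

    def test_large_tables_get_chi2(self):
        assert ss.choose_two_proportion_test((151, 184, 185, 96)) == "chi2"

    def test_dispatch_runs_selected_test(self):
        res = ss.run_two_proportion_test((7, 3, 0, 5), "auto", per_sample=True)
        assert res.test_name == "barnard_exact_two_tailed"
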