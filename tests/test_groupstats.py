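"""Nonparametric inference: ranks, Kruskal-Wallis, DSCF, Levene, IQR rules.

The Kruskal-Wallis H and the DSCF pair statistics are checked against
exhaustive permutation oracles and against independent reference
implementations (scipy) on the same data.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from accomstep import (GroupSample, dscf_pairwise, iqr_outliers, kruskal_wallis,
                       levene_test, main_effect_workflow, ranks_with_ties,
                       shapiro_wilk)


def g(label, values):
    return GroupSample(label, np.asarray(values, dtype=float))


class TestRanks:
    def test_distinct(self):
        np.testing.assert_array_equal(ranks_with_ties([3, 1, 2]), [3, 1, 2])

    def test_midranks(self):
        np.testing.assert_array_equal(ranks_with_ties([1, 2, 2, 3]), [1, 2.5, 2.5, 4])

    def test_all_tied(self):
        np.testing.assert_array_equal(ranks_with_ties([7] * 5), [3] * 5)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
    def test_rank_sum_identity(self, values):
        n = len(values)
        assert ranks_with_ties(values).sum() == pytest.approx(n * (n + 1) / 2)


def _kw_h(groups_values):
    """Independent direct evaluation of tie-corrected H for the oracle."""
    pooled = np.concatenate(groups_values)
    N = pooled.size
    r = sps.rankdata(pooled)
    start, ssq = 0, 0.0
    for v in groups_values:
        ri = r[start:start + len(v)]
        start += len(v)
        ssq += len(v) * (ri.mean() - (N + 1) / 2) ** 2
    _, t = np.unique(pooled, return_counts=True)
    C = 1 - np.sum(t**3 - t) / (N**3 - N)
    return 12 / (N * (N + 1)) * ssq / C


class TestKruskalWallis:
    def test_seven_groups_df_six(self):
        rng = np.random.default_rng(0)
        groups = [g(str(i), rng.normal(size=10)) for i in range(7)]
        assert kruskal_wallis(groups).df == 6

    def test_all_identical_degenerate(self):
        res = kruskal_wallis([g("a", [1, 1, 1]), g("b", [1, 1])])
        assert res.H == 0.0 and res.p == 1.0

    def test_exact_permutation_oracle_three_groups_of_three(self):
        # enumerate all 9!/(3!3!3!) = 1680 assignments of the pooled values
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        observed = kruskal_wallis([g("a", values[:3]), g("b", values[3:6]), g("c", values[6:])])
        assert observed.H == pytest.approx(_kw_h([values[:3], values[3:6], values[6:]]))
        assert observed.H == pytest.approx(7.2)
        stats = []
        idx = set(range(9))
        for a in combinations(range(9), 3):
            rest = idx - set(a)
            for b in combinations(sorted(rest), 3):
                c = sorted(rest - set(b))
                stats.append(_kw_h([values[list(a)], values[list(b)], values[list(c)]]))
        stats = np.array(stats)
        assert stats.size == 1680
        # perfectly separated groups attain the maximum of the permutation
        # distribution: exact tail = 3!/1680 (label permutations only)
        assert observed.H == pytest.approx(stats.max())
        exact_p = np.mean(stats >= observed.H - 1e-12)
        assert exact_p == pytest.approx(6 / 1680)
        # the implemented p is the chi-square approximation of that tail
        assert observed.p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (8, 11, 9, 7)]
        ours = kruskal_wallis([g(str(i), v) for i, v in enumerate(groups)])
        ref = sps.kruskal(*groups)
        assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=n) for n in (6, 8, 7)]
        h1 = kruskal_wallis([g(str(i), v) for i, v in enumerate(groups)]).H
        h2 = kruskal_wallis([g(str(i), np.exp(v)) for i, v in enumerate(groups)]).H
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_k2_equals_squared_ranksum_deviate(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, size=12).astype(float)
        b = rng.integers(0, 10, size=9).astype(float)
        H = kruskal_wallis([g("a", a), g("b", b)]).H
        pooled = np.concatenate([a, b])
        r = sps.rankdata(pooled)
        N = pooled.size
        T = r[:12].sum()
        var = 12 * 9 / (N * (N - 1)) * (np.sum(r**2) - N * (N + 1) ** 2 / 4)
        z = (T - 12 * (N + 1) / 2) / np.sqrt(var)
        assert H == pytest.approx(z**2, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="b"):
            kruskal_wallis([g("a", [1, 2, 3]), g("b", [1])])


class TestDSCF:
    def test_identical_groups_null(self):
        res = dscf_pairwise([g("a", [1, 2]), g("b", [1, 2])])
        assert len(res) == 1
        assert res[0].W == 0.0 and res[0].p == 1.0

    def test_n_pairs(self):
        rng = np.random.default_rng(0)
        groups = [g(str(i), rng.normal(size=5)) for i in range(7)]
        assert len(dscf_pairwise(groups)) == 21

    def test_pair_statistic_matches_enumeration_oracle(self):
        # exact permutation moments of the rank sum over all C(8,4)=70 splits
        # must equal the analytic E[T_j] and tie-corrected Var used by W
        a = np.array([1.0, 3.0, 3.0, 7.0])
        b = np.array([2.0, 3.0, 8.0, 11.0])
        pooled = np.concatenate([a, b])
        r = sps.rankdata(pooled)
        sums = np.array([r[list(c)].sum() for c in combinations(range(8), 4)])
        assert sums.size == 70
        expect = 4 * (8 + 1) / 2
        var_exact = np.mean((sums - expect) ** 2)  # permutation variance
        var_formula = 4 * 4 / (8 * 7) * (np.sum(r**2) - 8 * 81 / 4)
        assert var_formula == pytest.approx(var_exact, rel=1e-12)
        res = dscf_pairwise([g("a", a), g("b", b), g("c", b + 100)])
        pair_ab = [p for p in res if set(p.pair) == {"a", "b"}][0]
        Tb = r[4:].sum()
        W_manual = np.sqrt(2) * (Tb - expect) / np.sqrt(var_formula)
        assert pair_ab.W == pytest.approx(W_manual, rel=1e-12)
        # unadjusted two-sample normal tail of |W|/sqrt(2) vs exact rank tail
        z = abs(pair_ab.W) / np.sqrt(2)
        exact_tail = np.mean(np.abs(sums - expect) >= abs(Tb - expect) - 1e-12)
        assert 2 * sps.norm.sf(z) == pytest.approx(exact_tail, abs=0.15)
        # familywise-adjusted p comes from the studentized-range law q_{k,inf}
        assert pair_ab.p == pytest.approx(
            sps.studentized_range.sf(abs(pair_ab.W), 3, np.inf), rel=1e-9)

    def test_p_invariant_under_shift_and_pair_order(self):
        rng = np.random.default_rng(8)
        a, b, c = (rng.normal(size=6) for _ in range(3))
        p1 = {frozenset(r.pair): r.p for r in dscf_pairwise([g("a", a), g("b", b), g("c", c)])}
        p2 = {frozenset(r.pair): r.p for r in dscf_pairwise([g("c", c + 5), g("b", b + 5), g("a", a + 5)])}
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], rel=1e-9)

    def test_all_tied_degenerate(self):
        res = dscf_pairwise([g("a", [2.0, 2.0]), g("b", [2.0, 2.0]), g("c", [2.0, 2.0])])
        assert all(r.degenerate and r.p == 1.0 for r in res)

    @given(st.integers(0, 500))
    def test_adjusted_p_never_anticonservative(self, seed):
        # familywise DSCF p must be >= the unadjusted pairwise normal p
        rng = np.random.default_rng(seed)
        groups = [g(str(i), rng.normal(i * 0.3, 1, size=6)) for i in range(3)]
        for r in dscf_pairwise(groups):
            unadjusted = 2 * sps.norm.sf(abs(r.W) / np.sqrt(2))
            assert r.p >= unadjusted - 1e-12


class TestLevene:
    def test_translated_groups_null(self):
        a = np.array([1.0, 2.0, 5.0, 6.0])
        W, p = levene_test([g("a", a), g("b", a + 10)])
        assert W == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_direct_formula_and_scipy(self):
        # unequal-spread groups, slightly perturbed so deviations are not
        # all equal within each group
        a = np.array([0.0, 2.0] * 5) + np.linspace(0, 0.3, 10)
        b = np.array([-10.0, 10.0] * 5) + np.linspace(0, 0.7, 10)
        W, p = levene_test([g("a", a), g("b", b)])
        # independent oracle: direct evaluation of the classical formula
        za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
        zbar = np.concatenate([za, zb]).mean()
        num = 10 * (za.mean() - zbar) ** 2 + 10 * (zb.mean() - zbar) ** 2
        den = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        assert W == pytest.approx((20 - 2) / (2 - 1) * num / den, rel=1e-12)
        ref = sps.levene(a, b, center="mean")
        assert W == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_deviations_unequal_spread_is_extreme(self):
        W, p = levene_test([g("a", np.array([0.0, 2.0] * 5)),
                            g("b", np.array([-10.0, 10.0] * 5))])
        assert W == np.inf and p == 0.0

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(scale=3, size=12)
        W1, _ = levene_test([g("a", a), g("b", b)])
        W2, _ = levene_test([g("a", a + 100), g("b", b - 7)])
        assert W1 == pytest.approx(W2, rel=1e-9)

    def test_median_center_is_brown_forsythe(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=11), rng.normal(scale=2, size=13)
        W, p = levene_test([g("a", a), g("b", b)], center="median")
        ref = sps.levene(a, b, center="median")
        assert W == pytest.approx(ref.statistic, rel=1e-12)


class TestShapiro:
    def test_normal_quantiles_high_W(self):
        n = 50
        sample = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        W, _ = shapiro_wilk(sample)
        assert W > 0.99

    def test_bimodal_rejected(self):
        W, p = shapiro_wilk(np.array([0.0] * 20 + [10.0] * 20))
        assert p < 0.05
        assert 0 < W <= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestIQROutliers:
    def test_single_extreme_flagged(self):
        # quartiles by linear interpolation: Q1=2, Q3=4, fences [-1, 7]
        flags = iqr_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_none_flagged(self):
        assert not iqr_outliers([5.0] * 6).any()

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=30)
        v[3] = 10.0
        np.testing.assert_array_equal(iqr_outliers(v), iqr_outliers(2.5 * v + 7))

    def test_small_sample_warns_no_flags(self):
        with pytest.warns(UserWarning):
            flags = iqr_outliers([1.0, 2.0, 100.0])
        assert not flags.any()


class TestWorkflow:
    def _groups(self, shifted=True, rng=None):
        rng = rng or np.random.default_rng(10)
        out = []
        for i in range(7):
            loc = i * (1.0 if shifted else 0.0)
            out.append(g(f"cue{i}", rng.normal(loc, 1, size=12)))
        return out

    def test_significant_main_effect_produces_21_pairs(self):
        inf = main_effect_workflow(self._groups(shifted=True))
        assert inf.kw.df == 6
        assert inf.main_effect_significant
        assert len(inf.pairwise) == 21

    def test_null_main_effect_empty_pairwise(self):
        inf = main_effect_workflow(self._groups(shifted=False, rng=np.random.default_rng(1)))
        if not inf.main_effect_significant:
            assert inf.pairwise == []

    def test_outliers_removed_before_tests(self):
        rng = np.random.default_rng(2)
        groups = [g("a", np.append(rng.normal(size=12), 50.0)), g("b", rng.normal(size=12))]
        inf = main_effect_workflow(groups)
        assert inf.outliers_removed["a"] >= 1
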