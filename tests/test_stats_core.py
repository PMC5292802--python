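import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hlassoc import (
    DegenerateTableError,
    adjust_bonferroni,
    adjust_fdr_bh,
    chi_square_test,
    fisher_exact_test,
    odds_ratio,
    permutation_empirical_p,
    table,
)

cells = st.integers(min_value=0, max_value=30)


def chi2_bruteforce(t):
    """Direct evaluation of sum (O-E)^2/E, independent of the implementation."""
    (a, b), (c, d) = t.counts
    n = a + b + c + d
    stat = 0.0
    for o, r, col in ((a, a + b, a + c), (b, a + b, b + d),
                      (c, c + d, a + c), (d, c + d, b + d)):
        e = r * col / n
        stat += (o - e) ** 2 / e
    return stat


def fisher_enumeration(t):
    """Exact two-sided p by integer enumeration over the margin class.

    Probabilities share the denominator C(N, r1); summing the numerators of
    every table at most as probable as the observed one is exact arithmetic.
    """
    r1, c1, n = t.r1, t.c1, t.n
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    nums = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k)
            for k in range(lo, hi + 1)}
    obs = nums[t.counts[0][0]]
    return sum(v for v in nums.values() if v <= obs) / math.comb(n, r1)


class TestChiSquare:
    def test_uniform_table_gives_zero(self):
        r = chi_square_test(table(15, 15, 15, 15))
        assert r.statistic == 0 and r.p_value == 1

    def test_worked_example(self):
        # all expected counts are 15; four terms of 25/15
        r = chi_square_test(table(10, 20, 20, 10))
        assert r.statistic == pytest.approx(20 / 3, rel=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(table(5, 0, 5, 0))

    @given(cells, cells, cells, cells)
    @settings(max_examples=200)
    def test_matches_bruteforce_and_scipy(self, a, b, c, d):
        t = table(a, b, c, d)
        if min(t.r1, t.r2, t.c1, t.c2) == 0:
            return
        r = chi_square_test(t)
        assert r.statistic == pytest.approx(chi2_bruteforce(t), rel=1e-10)
        stat, p, _, _ = sps.chi2_contingency(t.as_array(), correction=False)[:4]
        assert r.statistic == pytest.approx(stat, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-9)


class TestFisherExact:
    @pytest.mark.parametrize("t,expected", [
        (table(1, 3, 3, 1), 34 / 70),
        (table(0, 5, 5, 0), 2 / 252),
        (table(5, 5, 5, 5), 1.0),
    ])
    def test_worked_examples(self, t, expected):
        assert fisher_exact_test(t).p_value == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_test(table(0, 0, 3, 4)).p_value == 1.0

    @given(cells, cells, cells, cells)
    @settings(max_examples=200)
    def test_matches_enumeration_and_scipy(self, a, b, c, d):
        t = table(a, b, c, d)
        if t.n == 0:
            return
        p = fisher_exact_test(t).p_value
        assert p == pytest.approx(fisher_enumeration(t), rel=1e-9)
        # independent route: scipy's two-sided Fisher
        _, p_scipy = sps.fisher_exact(t.as_array(), alternative="two-sided")
        assert p == pytest.approx(p_scipy, rel=1e-7, abs=1e-12)

    @given(cells, cells, cells, cells)
    @settings(max_examples=100)
    def test_margin_class_probabilities_sum_to_one(self, a, b, c, d):
        t = table(a, b, c, d)
        if min(t.r1, t.r2, t.c1, t.c2) == 0:
            return
        lo, hi = max(0, t.c1 - t.r2), min(t.r1, t.c1)
        probs = sps.hypergeom.pmf(np.arange(lo, hi + 1), t.n, t.c1, t.r1)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestOddsRatio:
    def test_worked_examples(self):
        assert odds_ratio(table(20, 10, 10, 20))["effect"] == pytest.approx(4.0)
        assert odds_ratio(table(1, 1, 1, 1))["effect"] == pytest.approx(1.0)
        # zero cell: 0.5 is added everywhere first
        assert odds_ratio(table(10, 0, 10, 10))["effect"] == pytest.approx(21.0)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50))
    def test_row_transpose_reciprocity(self, a, b, c, d):
        orig = odds_ratio(table(a, b, c, d))["effect"]
        flipped = odds_ratio(table(c, d, a, b))["effect"]
        assert flipped == pytest.approx(1 / orig, rel=1e-12)

    def test_ci_contains_point_estimate(self):
        eff = odds_ratio(table(12, 7, 5, 20))
        assert eff["ci_low"] < eff["effect"] < eff["ci_high"]


class TestAdjustments:
    def test_bonferroni(self):
        assert adjust_bonferroni([0.5, 0.4]) == [1.0, 0.8]
        assert adjust_bonferroni([]) == []

    def test_bh_worked_example(self):
        assert adjust_fdr_bh([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_bh_identity_cases(self):
        assert adjust_fdr_bh([0.5]) == [0.5]
        assert adjust_fdr_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert adjust_fdr_bh([]) == []

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bh_between_raw_and_bonferroni(self, pvals):
        bh = adjust_fdr_bh(pvals)
        bonf = adjust_bonferroni(pvals)
        for p, q, pb in zip(pvals, bh, bonf):
            assert p - 1e-12 <= q <= pb + 1e-12

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bh_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        assert adjust_fdr_bh(pvals) == pytest.approx(list(expected), rel=1e-12)


class TestPermutation:
    def test_add_one_estimator_floor(self):
        # observed statistic beats every permutation: p = 1/(B+1)
        pheno = [1.0] * 10 + [2.0] * 10

        def run_tests(p):
            # observed ordering is uniquely extreme under this score
            return [0.0 if list(p) == pheno else 1.0]

        p = permutation_empirical_p(pheno, run_tests, B=99, seed=5)
        assert p[0] == pytest.approx(1 / 100)

    def test_shuffle_invariant_statistic_gives_one(self):
        pheno = [1.0, 1.0, 2.0, 2.0]
        p = permutation_empirical_p(pheno, lambda ph: [0.42], B=50, seed=1)
        assert p[0] == 1.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        pheno = rng.integers(1, 3, size=30).astype(float)
        scores = rng.random(30)

        def run_tests(ph):
            # p-value proxy: correlation-based score
            return [abs(float(np.corrcoef(ph, scores)[0, 1]))]

        p1 = permutation_empirical_p(pheno, run_tests, B=200, seed=7)
        p2 = permutation_empirical_p(pheno, run_tests, B=200, seed=7)
        assert (p1 == p2).all()

    def test_null_empirical_p_approximately_uniform(self):
        # exchangeable null: allele carriage independent of phenotype
        from hlassoc.stats_core import run_2x2

        # sample large enough that table discreteness (ties count as
        # extreme) no longer inflates the mean much above 1/2
        rng = np.random.default_rng(321)
        draws = []
        for rep in range(200):
            pheno = np.array([1.0] * 500 + [2.0] * 500)
            rng.shuffle(pheno)
            copies = rng.binomial(2, 0.2, size=1000)

            def run_tests(ph, copies=copies):
                case = ph == 2.0
                t = table(int(copies[case].sum()),
                          int((2 - copies[case]).sum()),
                          int(copies[~case].sum()),
                          int((2 - copies[~case]).sum()))
                return [run_2x2(t, "chisq").p_value]

            p = permutation_empirical_p(pheno, run_tests, B=199, seed=rep)
            draws.append(p[0])
        assert 0.45 <= np.mean(draws) <= 0.55

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            permutation_empirical_p([1.0, 2.0], lambda p: [0.5], B=0, seed=1)
        with pytest.raises(ValueError):
            permutation_empirical_p([1.0, 1.0], lambda p: [0.5], B=10, seed=1)
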