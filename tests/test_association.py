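import numpy as np
import pytest

from hlassoc import (
    AssocConfig,
    build_table,
    code_genotype,
    count_allele_carriage,
    fit_linear,
    fit_logistic,
    parse_allele_name,
    run_association,
)
from hlassoc.io_formats import CovariateTable
from conftest import make_table

A0101 = parse_allele_name("A*01:01")


class TestCarriageCounts:
    def test_homozygote(self):
        t = make_table([("C1", 2, [("A*01:01", "A*01:01")])], ["A"])
        cc = count_allele_carriage(t, "A", A0101)["case"]
        assert (cc.copies, cc.carriers, cc.two_copy_carriers) == (2, 1, 1)

    def test_heterozygote(self):
        t = make_table([("C1", 2, [("A*01:01", "A*02:01")])], ["A"])
        cc = count_allele_carriage(t, "A", A0101)["case"]
        assert (cc.copies, cc.carriers, cc.two_copy_carriers) == (1, 1, 0)

    def test_mixed_tally(self):
        t = make_table([
            ("C1", 2, [("A*01:01", "A*01:01")]),
            ("C2", 2, [("A*01:01", "A*02:01")]),
            ("C3", 2, [("A*02:01", "A*02:01")]),
        ], ["A"])
        cc = count_allele_carriage(t, "A", A0101)["case"]
        assert (cc.copies, cc.carriers, cc.two_copy_carriers) == (3, 2, 1)


class TestBuildTable:
    @pytest.fixture
    def counts(self):
        rows = [(f"C{i}", 2, [("A*01:01", "A*02:01")]) for i in range(10)]
        rows += [(f"K{i}", 1, [("A*02:01", "A*02:01")]) for i in range(10)]
        return count_allele_carriage(make_table(rows, ["A"]), "A", A0101)

    def test_allelic(self, counts):
        assert build_table(counts, "allelic").counts == ((10, 10), (0, 20))

    def test_dominant(self, counts):
        assert build_table(counts, "dominant").counts == ((10, 0), (0, 10))

    def test_recessive(self, counts):
        assert build_table(counts, "recessive").counts == ((0, 10), (0, 10))


class TestCodeGenotype:
    @pytest.mark.parametrize("copies,model,code", [
        (2, "additive", 2), (2, "dominant", 1), (2, "recessive", 1),
        (1, "additive", 1), (1, "dominant", 1), (1, "recessive", 0),
        (0, "additive", 0), (0, "dominant", 0), (0, "recessive", 0),
    ])
    def test_coding_table(self, copies, model, code):
        assert code_genotype(copies, model) == code

    def test_dominant_and_recessive_bounded_by_additive(self):
        for copies in (0, 1, 2):
            add = code_genotype(copies, "additive")
            assert code_genotype(copies, "dominant") <= max(add, 1)
            assert code_genotype(copies, "recessive") <= add


class TestRunAssociation:
    def test_one_result_per_common_allele(self, toy_table):
        cfg = AssocConfig(method="chisq", model="allelic", min_count=1)
        results = run_association(toy_table, cfg)
        assert len(results) == 3  # the three observed alleles

    def test_min_count_filter_drops_rare_allele(self, toy_table):
        cfg = AssocConfig(method="fisher", min_count=5)
        labels = {r.label for r in run_association(toy_table, cfg)}
        assert "A:A*01:01" in labels
        # A*01:01 has 5 copies, A*02:01 has 6, A*03:01 has 5
        cfg6 = AssocConfig(method="fisher", min_count=6)
        labels6 = {r.label for r in run_association(toy_table, cfg6)}
        assert labels6 == {"A:A*02:01"}

    def test_no_common_allele_returns_empty(self, toy_table):
        cfg = AssocConfig(method="fisher", min_count=100)
        assert run_association(toy_table, cfg) == []

    def test_results_sorted_by_locus_then_p(self, toy_table):
        cfg = AssocConfig(method="fisher", min_count=1)
        ps = [r.p_value for r in run_association(toy_table, cfg)]
        assert ps == sorted(ps)

    def test_permutation_deterministic(self, toy_table):
        cfg = AssocConfig(method="fisher", min_count=1,
                          adjust="permutation", B=49, seed=11)
        r1 = run_association(toy_table, cfg)
        r2 = run_association(toy_table, cfg)
        assert [r.p_adjusted for r in r1] == [r.p_adjusted for r in r2]
        assert all(0 < r.p_adjusted <= 1 for r in r1)

    def test_incompatible_trait_method_rejected(self, toy_table):
        with pytest.raises(ValueError, match="quantitative"):
            run_association(toy_table, AssocConfig(method="linear"))

    def test_allelic_column_totals_conserve_copies(self, toy_table):
        cfg = AssocConfig(method="fisher", model="allelic", min_count=1)
        results = run_association(toy_table, cfg)
        # each allelic table's case row sums to total typed case copies
        for r in results:
            assert r.table.r1 == 8 and r.table.r2 == 8
        case_copies = sum(r.table.counts[0][0] for r in results)
        assert case_copies == 8  # every case copy is counted exactly once


class TestLogistic:
    def test_null_slope_small(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500)
        x = rng.integers(0, 3, 500)
        res = fit_logistic(y, x)
        assert res.note is None
        assert abs(np.log(res.effect)) < 0.5
        assert res.p_value > 0.01

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.binomial(2, 0.3, n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.7 * x)))
        y = (rng.random(n) < p).astype(float)
        res = fit_logistic(y, x)
        assert np.log(res.effect) == pytest.approx(0.7, abs=0.15)

    def test_constant_outcome_flagged(self):
        res = fit_logistic([1, 1, 1, 1], [0, 1, 2, 0])
        assert res.degenerate

    def test_perfect_separation_flagged(self):
        y = [0] * 10 + [1] * 10
        x = [0] * 10 + [2] * 10
        assert fit_logistic(y, x).degenerate

    def test_covariate_coefficient_count(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.integers(0, 3, n)
        covs = rng.normal(size=(n, 2))
        y = rng.integers(0, 2, n)
        res = fit_logistic(y, x, covs)
        assert len(res.extra["beta"]) == 4  # intercept + x + 2 covariates


class TestLinear:
    def test_noiseless_line(self):
        x = np.array([0, 1, 2, 0, 1, 2])
        res = fit_linear(3 + 2 * x, x)
        assert res.extra["beta"][0] == pytest.approx(3.0)
        assert res.effect == pytest.approx(2.0)
        assert res.extra["residual_variance"] == pytest.approx(0.0, abs=1e-20)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.binomial(2, 0.3, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        res = fit_linear(y, x)
        assert res.effect == pytest.approx(0.5, abs=0.1)

    def test_constant_x_flagged(self):
        res = fit_linear([1.0, 2.0, 3.0, 2.5], [1, 1, 1, 1])
        assert res.degenerate


def test_regression_run_with_covariate_file(toy_table):
    cov = CovariateTable(names=["age"],
                         values={s: [float(i)] for i, s in
                                 enumerate(toy_table.samples)})
    cfg = AssocConfig(method="logistic", model="additive", min_count=1)
    results = run_association(toy_table, cfg, covariates=cov)
    assert len(results) == 3
    assert all(r.method == "logistic" for r in results)


def test_chisq_and_logistic_agree_in_direction():
    rng = np.random.default_rng(9)
    agree = 0
    for rep in range(100):
        rows = []
        for i in range(60):
            is_case = i < 30
            p = 0.45 if is_case else 0.2
            a1 = "A*01:01" if rng.random() < p else "A*02:01"
            a2 = "A*01:01" if rng.random() < p else "A*02:01"
            rows.append((f"S{i}", 2 if is_case else 1, [(a1, a2)]))
        t = make_table(rows, ["A"])
        chi = run_association(t, AssocConfig(method="chisq", model="allelic",
                                             min_count=1))
        logi = run_association(t, AssocConfig(method="logistic",
                                              model="additive", min_count=1))
        chi_or = {r.label: r.effect for r in chi}
        logi_or = {r.label: r.effect for r in logi if not r.degenerate}
        if all((chi_or[k] > 1) == (v > 1) for k, v in logi_or.items()
               if abs(np.log(v)) > 1e-6):
            agree += 1
    assert agree >= 95  # same direction of effect in essentially every run
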