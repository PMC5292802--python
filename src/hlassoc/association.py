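"""Per-allele case-control association tests.

Each common allele at a locus is tested against all other alleles grouped
together, under the allelic (gene-copy), dominant (carrier) or recessive
(two-copy carrier) 2x2 construction with a chi-square or Fisher exact test,
or by logistic (binary trait) / linear (quantitative trait) regression on the
0/1/2 genotype code with optional covariates. P-values can be adjusted by
Bonferroni, Benjamini-Hochberg FDR, or a phenotype-permutation empirical
p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from . import stats_core
from .io_formats import AlleleName, CovariateTable, GenotypeTable, truncate_resolution
from .stats_core import ContingencyTable2x2, TestResult, table as t2x2

logger = logging.getLogger("hlassoc")

MODELS = ("allelic", "dominant", "recessive", "additive")
METHODS = ("chisq", "fisher", "logistic", "linear")
ADJUSTMENTS = ("none", "bonferroni", "fdr", "permutation")


@dataclass
class AssocConfig:
    """Settings for one association run.

    ``min_count`` is the "common allele" floor: an allele enters testing only
    when its combined gene-copy count reaches it; rarer alleles stay pooled
    on the "other alleles" side of every table. ``digits_fields`` is the
    resolution in name fields (1 = two-digit, 2 = four-digit).
    """

    model: str = "allelic"
    method: str = "fisher"
    min_count: int = 5
    digits_fields: int = 2
    adjust: str = "none"
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.adjust not in ADJUSTMENTS:
            raise ValueError(
                f"adjust must be one of {ADJUSTMENTS}, got {self.adjust!r}"
            )

    def validate_trait(self, trait_type: str) -> None:
        if self.method == "linear" and trait_type != "quantitative":
            raise ValueError("linear regression requires a quantitative trait")
        if self.method in ("chisq", "fisher", "logistic") and trait_type != "binary":
            raise ValueError(f"method {self.method!r} requires a binary trait")


@dataclass
class CarriageCounts:
    """Gene-copy and carrier bookkeeping for one allele in one group."""

    copies: int = 0          # gene copies of the allele (homozygote adds 2)
    other_copies: int = 0    # gene copies of all other alleles
    carriers: int = 0        # individuals with >= 1 copy
    non_carriers: int = 0
    two_copy_carriers: int = 0


def copies_of(call, allele: AlleleName, digits_fields: int) -> int:
    """Copies (0/1/2) of ``allele`` in one genotype call, post-truncation."""
    return sum(
        1 for a in call if truncate_resolution(a, digits_fields) == allele
    )


def count_allele_carriage(
    table: GenotypeTable, locus: str, allele: AlleleName, digits_fields: int = 2,
    case_mask: Sequence[bool] | None = None,
) -> dict[str, CarriageCounts]:
    """Tally copies/carriers of ``allele`` at ``locus`` in cases and controls.

    Individuals with a missing call at the locus are skipped. ``case_mask``
    overrides the table's phenotype (used by the permutation engine).
    """
    j = table.locus_index(locus)
    out = {"case": CarriageCounts(), "control": CarriageCounts()}
    for i in range(table.n_samples):
        call = table.calls[i][j]
        if call is None:
            continue
        is_case = case_mask[i] if case_mask is not None else table.is_case(i)
        cc = out["case" if is_case else "control"]
        k = copies_of(call, allele, digits_fields)
        cc.copies += k
        cc.other_copies += 2 - k
        if k >= 1:
            cc.carriers += 1
            if k == 2:
                cc.two_copy_carriers += 1
        else:
            cc.non_carriers += 1
    return out


def build_table(
    counts: dict[str, CarriageCounts], model: str
) -> ContingencyTable2x2:
    """Assemble the 2x2 for one allele: rows case/control, columns factor +/-.

    allelic: copies of the allele vs copies of the others; dominant: carriers
    vs non-carriers; recessive: two-copy carriers vs everyone else.
    """
    ca, co = counts["case"], counts["control"]
    if model == "allelic":
        return t2x2(ca.copies, ca.other_copies, co.copies, co.other_copies)
    if model == "dominant":
        return t2x2(ca.carriers, ca.non_carriers, co.carriers, co.non_carriers)
    if model == "recessive":
        return t2x2(
            ca.two_copy_carriers, ca.carriers + ca.non_carriers - ca.two_copy_carriers,
            co.two_copy_carriers, co.carriers + co.non_carriers - co.two_copy_carriers,
        )
    raise ValueError(f"no 2x2 construction for model {model!r}")


def code_genotype(copies: int, model: str) -> int:
    """0/1/2 genotype code of the tested (risk) allele under a genetic model.

    additive: the copy number itself; dominant: 1 for any carrier;
    recessive: 1 only for the two-copy homozygote.
    """
    if copies not in (0, 1, 2):
        raise ValueError(f"copies must be 0, 1 or 2, got {copies}")
    if model == "additive":
        return copies
    if model == "dominant":
        return int(copies >= 1)
    if model == "recessive":
        return int(copies == 2)
    raise ValueError(f"unknown genetic model {model!r}")


# ---------------------------------------------------------------------------
# Regression fitters
# ---------------------------------------------------------------------------

def _design(x: np.ndarray, covs: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x, dtype=float), x.astype(float)]
    if covs is not None and covs.size:
        cols.extend(covs[:, k].astype(float) for k in range(covs.shape[1]))
    return np.column_stack(cols)


def _flagged(method: str, label: str, note: str) -> TestResult:
    return TestResult(method=method, p_value=1.0, label=label, note=note)


def fit_logistic(
    y: Sequence[int], x: Sequence[int], covs: np.ndarray | None = None,
    label: str = "",
) -> TestResult:
    """Maximum-likelihood logistic fit of disease on the genotype code.

    y is 1 for cases and 0 for controls; the model is
    logit Pr(y=1) = b0 + b1*x (+ covariate terms). Reports the Wald p-value
    of b1 and OR = exp(b1). Perfect separation or a rank-deficient design
    yields a flagged result rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.unique(y).size < 2:
        return _flagged("logistic", label, "degenerate: outcome is constant")
    X = _design(x, covs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _flagged("logistic", label, "degenerate: rank-deficient design")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # separation, non-convergence
        return _flagged("logistic", label, f"degenerate: {exc}")
    if not fit.mle_retvals.get("converged", True):
        return _flagged("logistic", label, "degenerate: MLE did not converge")
    b1, se1 = float(fit.params[1]), float(fit.bse[1])
    return TestResult(
        method="logistic", p_value=float(fit.pvalues[1]), label=label,
        effect=float(np.exp(b1)), effect_se=se1,
        ci_low=float(np.exp(b1 - 1.96 * se1)), ci_high=float(np.exp(b1 + 1.96 * se1)),
        extra={"beta": fit.params.tolist(), "se": fit.bse.tolist(),
               "coef_pvalues": fit.pvalues.tolist()},
    )


def fit_linear(
    y: Sequence[float], x: Sequence[int], covs: np.ndarray | None = None,
    label: str = "",
) -> TestResult:
    """Ordinary least squares fit of a quantitative trait on the genotype code.

    y = b0 + b1*x (+ covariates) + e. Reports b1, its standard error, the
    t-test p-value, and the residual variance. A rank-deficient design
    (e.g. constant x) yields a flagged result.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = _design(x, covs)
    if X.shape[0] <= X.shape[1]:
        return _flagged("linear", label, "degenerate: n <= number of parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _flagged("linear", label, "degenerate: rank-deficient design")
    fit = sm.OLS(y, X).fit()
    b1, se1 = float(fit.params[1]), float(fit.bse[1])
    return TestResult(
        method="linear", p_value=float(fit.pvalues[1]), label=label,
        effect=b1, effect_se=se1,
        ci_low=b1 - 1.96 * se1, ci_high=b1 + 1.96 * se1,
        extra={"beta": fit.params.tolist(), "se": fit.bse.tolist(),
               "coef_pvalues": fit.pvalues.tolist(),
               "residual_variance": float(fit.mse_resid)},
    )


# ---------------------------------------------------------------------------
# The per-allele run
# ---------------------------------------------------------------------------

def common_alleles(
    table: GenotypeTable, locus: str, digits_fields: int, min_count: int
) -> list[AlleleName]:
    """Alleles whose combined gene-copy count reaches ``min_count``, sorted."""
    from collections import Counter

    j = table.locus_index(locus)
    counts: Counter = Counter()
    for i in range(table.n_samples):
        call = table.calls[i][j]
        if call is None:
            continue
        for a in call:
            counts[truncate_resolution(a, digits_fields)] += 1
    return sorted((a for a, n in counts.items() if n >= min_count), key=str)


def _regression_inputs(
    table: GenotypeTable, locus: str, allele: AlleleName, config: AssocConfig,
    covariates: CovariateTable | None, phenotype: Sequence[float] | None = None,
):
    """y, x, covariate matrix for one allele, restricted to usable samples."""
    j = table.locus_index(locus)
    pheno = list(phenotype) if phenotype is not None else table.phenotype
    code_model = "additive" if config.model == "allelic" else config.model
    ys, xs, rows = [], [], []
    for i in range(table.n_samples):
        call = table.calls[i][j]
        if call is None:
            continue
        sid = table.samples[i]
        if covariates is not None and sid not in covariates.values:
            continue
        if table.trait_type == "binary":
            ys.append(1.0 if pheno[i] == 2 else 0.0)
        else:
            ys.append(float(pheno[i]))
        xs.append(code_genotype(copies_of(call, allele, config.digits_fields), code_model))
        rows.append(sid)
    covs = None
    if covariates is not None:
        covs = covariates.matrix(rows).to_numpy(dtype=float)
    return np.asarray(ys), np.asarray(xs), covs


def _one_test(
    table: GenotypeTable, locus: str, allele: AlleleName, config: AssocConfig,
    covariates: CovariateTable | None, case_mask: Sequence[bool] | None = None,
    phenotype: Sequence[float] | None = None,
) -> TestResult:
    label = f"{locus}:{allele}"
    if config.method in ("chisq", "fisher"):
        model = "allelic" if config.model == "additive" else config.model
        counts = count_allele_carriage(
            table, locus, allele, config.digits_fields, case_mask=case_mask
        )
        return stats_core.run_2x2(build_table(counts, model), config.method, label=label)
    y, x, covs = _regression_inputs(
        table, locus, allele, config, covariates, phenotype=phenotype
    )
    fit = fit_logistic if config.method == "logistic" else fit_linear
    return fit(y, x, covs, label=label)


def run_association(
    table: GenotypeTable,
    config: AssocConfig,
    covariates: CovariateTable | None = None,
) -> list[TestResult]:
    """Test every common allele at every locus; adjust and sort the results.

    One result per allele passing the ``min_count`` filter. Multiple-testing
    adjustment treats all tests of the run (all alleles across all loci) as
    one family. Ordering is deterministic: locus, then raw p ascending, ties
    broken by allele name.
    """
    config.validate_trait(table.trait_type)
    tested: list[tuple[str, AlleleName]] = []
    for locus in table.loci:
        alleles = common_alleles(table, locus, config.digits_fields, config.min_count)
        tested.extend((locus, a) for a in alleles)
    if not tested:
        logger.warning("no allele passes min_count=%d at any locus", config.min_count)
        return []

    results = [
        _one_test(table, locus, allele, config, covariates)
        for locus, allele in tested
    ]

    if config.adjust == "permutation":
        def run_tests(pheno: np.ndarray) -> list[float]:
            if table.trait_type == "binary":
                mask = [p == 2 for p in pheno]
                return [
                    _one_test(table, loc, a, config, covariates, case_mask=mask).p_value
                    for loc, a in tested
                ]
            return [
                _one_test(table, loc, a, config, covariates, phenotype=pheno).p_value
                for loc, a in tested
            ]

        emp = stats_core.permutation_empirical_p(
            table.phenotype, run_tests, config.B, config.seed
        )
        for res, p in zip(results, emp):
            res.p_adjusted = float(p)
    else:
        for res, p in zip(results, stats_core.adjust([r.p_value for r in results],
                                                     config.adjust)):
            res.p_adjusted = p

    locus_order = {loc: k for k, loc in enumerate(table.loci)}
    results.sort(key=lambda r: (locus_order[r.label.split(":", 1)[0]],
                                r.p_value, r.label))
    return results
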