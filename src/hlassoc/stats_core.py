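"""2x2 contingency-table tests and the multiple-testing layer.

Implements the Pearson chi-square test (no continuity correction, 1 degree of
freedom), the two-sided Fisher exact test by same-margin enumeration, the
odds ratio with Haldane-Anscombe zero-cell handling, and Bonferroni, the
Benjamini-Hochberg false discovery rate and phenotype-permutation empirical
p-value corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

#: Relative tolerance when comparing a table probability with the observed
#: one in the two-sided Fisher rule; float round-off must not drop ties.
FISHER_TIE_RTOL = 1e-7


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin, on which the chi-square test is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed counts of a 2x2 table: rows case/control, columns factor +/-.

    ``counts[0]`` is the case row ``(factor-positive, factor-negative)``;
    ``counts[1]`` the control row.
    """

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if any(v < 0 for row in self.counts for v in row):
            raise ValueError(f"negative cell count in {self.counts}")

    @property
    def r1(self) -> int:
        return self.counts[0][0] + self.counts[0][1]

    @property
    def r2(self) -> int:
        return self.counts[1][0] + self.counts[1][1]

    @property
    def c1(self) -> int:
        return self.counts[0][0] + self.counts[1][0]

    @property
    def c2(self) -> int:
        return self.counts[0][1] + self.counts[1][1]

    @property
    def n(self) -> int:
        return self.r1 + self.r2

    def expected(self) -> np.ndarray:
        """Expected cell counts r_i * c_j / N under independence."""
        if self.n == 0:
            raise DegenerateTableError("empty table")
        r = np.array([self.r1, self.r2], dtype=float)
        c = np.array([self.c1, self.c2], dtype=float)
        return np.outer(r, c) / self.n

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def table(a: int, b: int, c: int, d: int) -> ContingencyTable2x2:
    """Shorthand constructor: case row (a, b), control row (c, d)."""
    return ContingencyTable2x2(((a, b), (c, d)))


@dataclass
class TestResult:
    """Outcome of one association test.

    ``statistic`` is the chi-square value (None for Fisher), ``effect`` the
    odds ratio (2x2 tests) or regression coefficient, ``table`` the 2x2 the
    test was computed on (None for regression), and ``label`` names what was
    tested (allele, residue, factor pair ...).
    """

    method: str
    p_value: float
    label: str = ""
    statistic: float | None = None
    effect: float | None = None
    effect_se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    table: ContingencyTable2x2 | None = None
    p_adjusted: float | None = None
    note: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return self.note is not None and "degenerate" in self.note


# ---------------------------------------------------------------------------
# 2x2 tests
# ---------------------------------------------------------------------------

def chi_square_test(t: ContingencyTable2x2, label: str = "") -> TestResult:
    """Pearson chi-square test on a 2x2 table, 1 df, no continuity correction.

    statistic = sum over cells of (O - E)^2 / E; p is the upper chi-square
    tail. Raises :class:`DegenerateTableError` on a zero margin (callers may
    fall back to Fisher, which stays defined there).
    """
    if min(t.r1, t.r2, t.c1, t.c2) == 0:
        raise DegenerateTableError(f"zero margin in table {t.counts}")
    e = t.expected()
    o = t.as_array()
    statistic = float(((o - e) ** 2 / e).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    eff = odds_ratio(t)
    return TestResult(
        method="chisq", statistic=statistic, p_value=max(p, np.nextafter(0, 1)),
        label=label, table=t, **eff,
    )


def fisher_exact_test(t: ContingencyTable2x2, label: str = "") -> TestResult:
    """Two-sided Fisher exact test by enumeration over same-margin tables.

    The probability of the observed table under fixed margins is the
    hypergeometric ``P_cutoff``; the two-sided p-value sums the probabilities
    of every same-margin table whose probability is at most ``P_cutoff``
    (with a small relative tolerance so float ties are kept). Degenerate
    margins give p = 1.
    """
    if t.n < 1:
        raise ValueError("Fisher test needs N >= 1")
    if min(t.r1, t.r2, t.c1, t.c2) == 0:
        # only one table has these margins
        return TestResult(
            method="fisher", p_value=1.0, label=label, table=t, **odds_ratio(t),
        )
    lo = max(0, t.c1 - t.r2)
    hi = min(t.r1, t.c1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, t.n, t.c1, t.r1)
    p_cutoff = probs[t.counts[0][0] - lo]
    p = float(probs[probs <= p_cutoff * (1 + FISHER_TIE_RTOL)].sum())
    return TestResult(
        method="fisher", p_value=min(p, 1.0), label=label, table=t, **odds_ratio(t),
    )


def odds_ratio(t: ContingencyTable2x2) -> dict:
    """Odds ratio ad/bc with the Haldane-Anscombe correction on zero cells.

    When any cell is 0, 0.5 is added to all four cells before the
    cross-product. Returns ``effect`` (OR), ``effect_se`` (SE of log OR) and
    the Wald 95% CI bounds, keyed to match :class:`TestResult` fields.
    """
    if t.n < 1:
        raise ValueError("odds ratio needs N >= 1")
    cells = t.as_array()
    if (cells == 0).any():
        cells = cells + 0.5
    (a, b), (c, d) = cells
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1 / cells).sum()))
    log_or = np.log(or_)
    return {
        "effect": float(or_),
        "effect_se": se,
        "ci_low": float(np.exp(log_or - 1.96 * se)),
        "ci_high": float(np.exp(log_or + 1.96 * se)),
    }


def run_2x2(t: ContingencyTable2x2, method: str, label: str = "") -> TestResult:
    """Dispatch to the chosen 2x2 test, flagging degenerate tables.

    A zero-margin table under ``chisq`` yields a flagged result (p = 1,
    note set) rather than an exception, so batch runs keep going.
    """
    if method == "fisher":
        return fisher_exact_test(t, label=label)
    if method == "chisq":
        try:
            return chi_square_test(t, label=label)
        except DegenerateTableError as exc:
            return TestResult(
                method="chisq", p_value=1.0, label=label, table=t,
                note=f"degenerate: {exc}",
            )
    raise ValueError(f"unknown 2x2 method {method!r}")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def adjust_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: min(1, m * p), order preserved."""
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


def adjust_fdr_bh(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sorted ascending, q_(i) = p_(i) * m / i, made monotone from the largest
    rank down, capped at 1.
    """
    m = len(pvals)
    if m == 0:
        return []
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out.tolist()


def adjust(pvals: Sequence[float], method: str) -> list[float] | list[None]:
    if method == "none":
        return [None] * len(pvals)
    if method == "bonferroni":
        return adjust_bonferroni(pvals)
    if method == "fdr":
        return adjust_fdr_bh(pvals)
    raise ValueError(f"unknown adjustment {method!r}")


def permutation_empirical_p(
    phenotype: Sequence[float],
    run_tests: Callable[[np.ndarray], Sequence[float]],
    B: int,
    seed: int,
) -> np.ndarray:
    """Empirical p-values by phenotype permutation.

    ``run_tests`` maps a phenotype vector (aligned to the dataset's samples,
    which stay fixed) to the vector of per-test p-values. Phenotype labels
    are shuffled ``B`` times with one seeded generator; every test of the run
    sees the same shuffles, preserving the correlation structure among
    alleles. Extremeness is measured on the p-value scale (permuted p <=
    observed p), and the add-one estimator (b + 1) / (B + 1) keeps the result
    in (0, 1].
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pheno = np.asarray(phenotype, dtype=float)
    if np.unique(pheno).size < 2:
        raise ValueError("permutation needs >= 2 distinct phenotype values")
    observed = np.asarray(run_tests(pheno), dtype=float)
    rng = np.random.default_rng(seed)
    b = np.zeros_like(observed)
    for _ in range(B):
        permuted = rng.permutation(pheno)
        b += np.asarray(run_tests(permuted), dtype=float) <= observed
    return (b + 1) / (B + 1)
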