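"""Two-factor interaction battery: eight 2x2 tests.

Individuals typed for both factors are cross-classified by carrier status
(>= 1 copy) of factor A and factor B into eight cells — a..d in cases,
e..h in controls — and eight 2x2 tests probe independence, differential
association, combined association and linkage disequilibrium:

* T1/T2 — each factor vs disease, ignoring the other (independence);
* T3/T4 — A vs disease within B+ and within B- strata (differential /
  combined association of A given B), T5/T6 likewise for B given A;
* T7/T8 — A vs B within cases and within controls (LD on each side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import stats_core
from .factors import AlleleFactor, ResidueFactor
from .io_formats import AAAlignment, GenotypeTable
from .stats_core import TestResult, table as t2x2

logger = logging.getLogger("hlassoc")

TEST_NAMES = {
    "T1": "factor A vs disease",
    "T2": "factor B vs disease",
    "T3": "A vs disease among B+",
    "T4": "A vs disease among B-",
    "T5": "B vs disease among A+",
    "T6": "B vs disease among A-",
    "T7": "A vs B in cases (LD)",
    "T8": "A vs B in controls (LD)",
}


@dataclass(frozen=True)
class EightFoldCounts:
    """Cases a..d and controls e..h by (A+/-, B+/-) carrier status.

    a = A+B+ cases, b = A+B- cases, c = A-B+ cases, d = A-B- cases;
    e..h the same in controls.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int
    g: int
    h: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.a, self.b, self.c, self.d,
                               self.e, self.f, self.g, self.h)):
            raise ValueError("negative cell count")

    @property
    def n_cases(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_controls(self) -> int:
        return self.e + self.f + self.g + self.h


def _factor_copies(factor, call, aln):
    if isinstance(factor, ResidueFactor):
        return factor.copies(call, aln)
    return factor.copies(call)


def cross_classify(
    table: GenotypeTable,
    factor_a: AlleleFactor | ResidueFactor,
    factor_b: AlleleFactor | ResidueFactor,
    aln: AAAlignment | None = None,
) -> EightFoldCounts:
    """Count the eight-fold cross-classification of two factors.

    Positivity = carriage (>= 1 copy); zygosity is not distinguished here.
    Individuals untyped for either factor are excluded with a log note.
    """
    locus_a = factor_a.gene if isinstance(factor_a, ResidueFactor) else factor_a.locus
    locus_b = factor_b.gene if isinstance(factor_b, ResidueFactor) else factor_b.locus
    ja, jb = table.locus_index(locus_a), table.locus_index(locus_b)
    cells = {k: 0 for k in "abcdefgh"}
    excluded = 0
    for i in range(table.n_samples):
        ka = _factor_copies(factor_a, table.calls[i][ja], aln)
        kb = _factor_copies(factor_b, table.calls[i][jb], aln)
        if ka is None or kb is None:
            excluded += 1
            continue
        offset = 0 if table.is_case(i) else 4
        idx = (0 if ka >= 1 else 2) + (0 if kb >= 1 else 1) + offset
        cells["abcdefgh"[idx]] += 1
    if excluded:
        logger.warning(
            "interaction %s x %s: %d individual(s) excluded (untyped for a factor)",
            factor_a, factor_b, excluded,
        )
    return EightFoldCounts(**cells)


def interaction_tables(counts: EightFoldCounts) -> dict[str, stats_core.ContingencyTable2x2]:
    """The eight 2x2 tables of the two-factor battery."""
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    e, f, g, h = counts.e, counts.f, counts.g, counts.h
    return {
        "T1": t2x2(a + b, c + d, e + f, g + h),
        "T2": t2x2(a + c, b + d, e + g, f + h),
        "T3": t2x2(a, c, e, g),
        "T4": t2x2(b, d, f, h),
        "T5": t2x2(a, b, e, f),
        "T6": t2x2(c, d, g, h),
        "T7": t2x2(a, b, c, d),
        "T8": t2x2(e, f, g, h),
    }


def interaction_tests(
    counts: EightFoldCounts, method: str = "fisher", label_prefix: str = ""
) -> list[TestResult]:
    """Run the chosen 2x2 test on each of the eight tables.

    Degenerate tables (zero margin under chisq) are flagged individually;
    the remaining tests are unaffected.
    """
    results = []
    for name, t in interaction_tables(counts).items():
        label = f"{label_prefix}{name} ({TEST_NAMES[name]})"
        results.append(stats_core.run_2x2(t, method, label=label))
    return results
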