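"""Homozygous, heterozygous and zygosity association tests.

For one factor (an allele, or a residue at an alignment position) every typed
individual is exactly one of homozygous (two copies), heterozygous (one
copy) or absent (none). At the amino-acid level two *different* alleles that
code for the same residue still make a homozygote. Three 2x2 tests compare
the groups between cases and controls:

* homozygous test — homozygous vs absent,
* heterozygous test — heterozygous vs absent,
* zygosity test — homozygous vs heterozygous (carriers only).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import stats_core
from .factors import AlleleFactor, ResidueFactor
from .io_formats import AAAlignment, GenotypeTable
from .stats_core import TestResult, table as t2x2

STATES = ("homozygous", "heterozygous", "absent")


@dataclass(frozen=True)
class CarrierState:
    state: str  # homozygous | heterozygous | absent

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")


def carrier_state(
    call, factor: AlleleFactor | ResidueFactor, aln: AAAlignment | None = None
) -> CarrierState | None:
    """Classify one genotype call against a factor; None = excluded.

    Allele level: 2 copies -> homozygous, 1 -> heterozygous, 0 -> absent.
    Residue level: both gene copies code for the residue -> homozygous
    (the two alleles need not be identical), exactly one -> heterozygous.
    """
    if isinstance(factor, ResidueFactor):
        if aln is None:
            raise ValueError("residue factor needs an alignment")
        k = factor.copies(call, aln)
    else:
        k = factor.copies(call)
    if k is None:
        return None
    return CarrierState(STATES[2 - k])


def classify(
    table: GenotypeTable, factor: AlleleFactor | ResidueFactor,
    aln: AAAlignment | None = None,
) -> dict[str, dict[str, int]]:
    """Per group, the number of homozygous/heterozygous/absent individuals."""
    locus = factor.gene if isinstance(factor, ResidueFactor) else factor.locus
    j = table.locus_index(locus)
    out = {g: {s: 0 for s in STATES} for g in ("case", "control")}
    for i in range(table.n_samples):
        st = carrier_state(table.calls[i][j], factor, aln)
        if st is None:
            continue
        out["case" if table.is_case(i) else "control"][st.state] += 1
    return out


def zygosity_tests(
    table: GenotypeTable, factor: AlleleFactor | ResidueFactor,
    method: str = "fisher", aln: AAAlignment | None = None,
) -> list[TestResult]:
    """The three zygosity 2x2 tests for one factor, rows case/control.

    A table with an empty margin is flagged degenerate (p = 1, note set)
    while the other tests are still returned.
    """
    counts = classify(table, factor, aln)
    ca, co = counts["case"], counts["control"]
    layouts = [
        ("homozygous", t2x2(ca["homozygous"], ca["absent"],
                            co["homozygous"], co["absent"])),
        ("heterozygous", t2x2(ca["heterozygous"], ca["absent"],
                              co["heterozygous"], co["absent"])),
        ("zygosity", t2x2(ca["homozygous"], ca["heterozygous"],
                          co["homozygous"], co["heterozygous"])),
    ]
    results = []
    for name, t in layouts:
        label = f"{factor}:{name}"
        if min(t.r1, t.r2, t.c1, t.c2) == 0:
            results.append(TestResult(
                method=method, p_value=1.0, label=label, table=t,
                note="degenerate: zero margin",
            ))
        else:
            results.append(stats_core.run_2x2(t, method, label=label))
    return results
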