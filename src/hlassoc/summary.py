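"""Gene-, allele- and population-level frequency summaries.

Allele frequencies are gene-copy frequencies (a homozygote contributes two
copies), stratified into case, control and combined groups for binary traits;
a quantitative trait yields the combined summary only. The population-level
summary is the number of distinct alleles and the typing completeness per
locus and group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AlleleName, GenotypeTable, truncate_resolution

GROUPS = ("case", "control", "combined")


@dataclass
class FrequencySummary:
    """Counts and frequencies per (locus, allele, group).

    ``allele_counts[group][locus]`` maps allele -> gene-copy count;
    ``typed[group][locus]`` / ``missing[group][locus]`` count individuals.
    """

    loci: list[str]
    groups: tuple[str, ...]
    allele_counts: dict[str, dict[str, Counter]] = field(default_factory=dict)
    typed: dict[str, dict[str, int]] = field(default_factory=dict)
    missing: dict[str, dict[str, int]] = field(default_factory=dict)

    def total_copies(self, group: str, locus: str) -> int:
        return sum(self.allele_counts[group][locus].values())

    def frequency(self, group: str, locus: str, allele: AlleleName) -> float:
        total = self.total_copies(group, locus)
        return self.allele_counts[group][locus][allele] / total if total else 0.0

    def distinct_alleles(self, group: str, locus: str) -> int:
        return sum(1 for v in self.allele_counts[group][locus].values() if v > 0)

    def allele_frame(self) -> pd.DataFrame:
        """Long-format allele table, ordered by locus, then descending
        combined frequency, then allele name."""
        rows = []
        for locus in self.loci:
            combined = self.allele_counts["combined"][locus]
            alleles = sorted(
                combined, key=lambda a: (-self.frequency("combined", locus, a), str(a))
            )
            for allele in alleles:
                row = {"locus": locus, "allele": str(allele)}
                for g in self.groups:
                    row[f"count_{g}"] = self.allele_counts[g][locus][allele]
                    row[f"freq_{g}"] = self.frequency(g, locus, allele)
                rows.append(row)
        return pd.DataFrame(rows)

    def locus_frame(self) -> pd.DataFrame:
        """Per-locus typing completeness and allele diversity."""
        rows = []
        for locus in self.loci:
            row = {"locus": locus}
            for g in self.groups:
                row[f"typed_{g}"] = self.typed[g][locus]
                row[f"missing_{g}"] = self.missing[g][locus]
                row[f"distinct_alleles_{g}"] = self.distinct_alleles(g, locus)
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(table: GenotypeTable, digits_fields: int = 2) -> FrequencySummary:
    """Count allele copies per locus and group at the requested resolution.

    Alleles are truncated to ``digits_fields`` name fields before counting.
    Individuals missing a call at a locus are excluded from that locus's
    totals and counted in its missing tally.
    """
    if table.n_samples == 0:
        raise ValueError("empty genotype table")
    groups = GROUPS if table.trait_type == "binary" else ("combined",)
    summ = FrequencySummary(loci=list(table.loci), groups=groups)
    for g in groups:
        summ.allele_counts[g] = {loc: Counter() for loc in table.loci}
        summ.typed[g] = {loc: 0 for loc in table.loci}
        summ.missing[g] = {loc: 0 for loc in table.loci}

    for i in range(table.n_samples):
        my_groups = ["combined"]
        if table.trait_type == "binary":
            my_groups.append("case" if table.is_case(i) else "control")
        for j, locus in enumerate(table.loci):
            call = table.calls[i][j]
            for g in my_groups:
                if call is None:
                    summ.missing[g][locus] += 1
                    continue
                summ.typed[g][locus] += 1
                for allele in call:
                    summ.allele_counts[g][locus][
                        truncate_resolution(allele, digits_fields)
                    ] += 1
    return summ
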