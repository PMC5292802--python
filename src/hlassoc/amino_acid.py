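"""Amino-acid level association: residue occurrence at alignment positions.

Each carried allele is mapped to its aligned residue at every alignment
column, and residue occurrence is compared between cases and controls with
the same allelic/dominant/recessive 2x2 constructions used at allele level —
"residue at position" simply replaces "allele" as the tested factor. The
indel state '-' is an ordinary testable residue class; the unknown state '*'
excludes the affected gene copies (allelic) or individuals (carrier models)
from the position's totals.
"""

from __future__ import annotations

import logging
from collections import Counter

from . import stats_core
from .association import AssocConfig
from .io_formats import AAAlignment, AA_UNKNOWN, GenotypeTable
from .stats_core import TestResult, table as t2x2

logger = logging.getLogger("hlassoc")


def residues_for_individual(
    call, aln: AAAlignment, position: int
) -> tuple[str, str] | None:
    """The two residues an individual's allele pair codes for at a column.

    Returns None (exclusion) when either allele is absent from the alignment
    at its resolution; unknown residues ('*') are returned as-is and handled
    by the counting layer.
    """
    residues = tuple(aln.residue(a, position) for a in call)
    if any(r is None for r in residues):
        return None
    return residues  # type: ignore[return-value]


def _position_counts(
    table: GenotypeTable, aln: AAAlignment, position: int
) -> tuple[dict[str, Counter], dict[str, Counter], dict[str, Counter]]:
    """Per group: residue copy counts, carrier counts, homozygote counts.

    Copy counts are per gene copy ('*' copies dropped); carrier/homozygote
    counts are per individual and require both residues known.
    """
    j = table.locus_index(aln.gene)
    copies = {"case": Counter(), "control": Counter()}
    carriers = {"case": Counter(), "control": Counter()}
    homozygotes = {"case": Counter(), "control": Counter()}
    typed = {"case": 0, "control": 0}
    excluded = 0
    for i in range(table.n_samples):
        call = table.calls[i][j]
        if call is None:
            continue
        pair = residues_for_individual(call, aln, position)
        if pair is None:
            excluded += 1
            continue
        g = "case" if table.is_case(i) else "control"
        for r in pair:
            if r != AA_UNKNOWN:
                copies[g][r] += 1
        if AA_UNKNOWN not in pair:
            typed[g] += 1
            for r in set(pair):
                carriers[g][r] += 1
            if pair[0] == pair[1]:
                homozygotes[g][pair[0]] += 1
    if excluded:
        logger.warning(
            "%s position %d: %d individual(s) excluded (allele not in alignment)",
            aln.gene, position, excluded,
        )
    return copies, carriers, homozygotes, typed  # type: ignore[return-value]


def aa_association(
    table: GenotypeTable, aln: AAAlignment, config: AssocConfig
) -> list[TestResult]:
    """Test every observed residue at every alignment column of one gene.

    For each column, each residue with combined copy count >= ``min_count``
    gets one 2x2 test under the configured model; monomorphic columns (a
    single residue class observed) emit no test. Results are labelled
    ``gene:pos<column>:<residue>`` and sorted by column, then raw p, then
    residue. Adjustment (Bonferroni/FDR) treats the whole run as one family.
    """
    if config.method not in ("chisq", "fisher"):
        raise ValueError("amino-acid association supports chisq or fisher")
    if config.adjust == "permutation":
        raise ValueError(
            "permutation adjustment is available for allele-level runs only"
        )
    config.validate_trait(table.trait_type)
    model = "allelic" if config.model == "additive" else config.model
    results: list[TestResult] = []
    for position in range(1, aln.length + 1):
        copies, carriers, homozygotes, typed = _position_counts(table, aln, position)
        observed = sorted(set(copies["case"]) | set(copies["control"]))
        if len(observed) < 2:
            continue  # monomorphic: nothing to compare
        for residue in observed:
            total = copies["case"][residue] + copies["control"][residue]
            if total < config.min_count:
                continue
            if model == "allelic":
                t = t2x2(
                    copies["case"][residue],
                    sum(copies["case"].values()) - copies["case"][residue],
                    copies["control"][residue],
                    sum(copies["control"].values()) - copies["control"][residue],
                )
            elif model == "dominant":
                t = t2x2(
                    carriers["case"][residue],
                    typed["case"] - carriers["case"][residue],
                    carriers["control"][residue],
                    typed["control"] - carriers["control"][residue],
                )
            else:  # recessive
                t = t2x2(
                    homozygotes["case"][residue],
                    typed["case"] - homozygotes["case"][residue],
                    homozygotes["control"][residue],
                    typed["control"] - homozygotes["control"][residue],
                )
            results.append(
                stats_core.run_2x2(
                    t, config.method, label=f"{aln.gene}:pos{position}:{residue}"
                )
            )
    for res, p in zip(
        results, stats_core.adjust([r.p_value for r in results], config.adjust)
    ):
        res.p_adjusted = p

    def _key(r: TestResult):
        _, pos_tok, residue = r.label.split(":")
        return (int(pos_tok[3:]), r.p_value, residue)

    results.sort(key=_key)
    return results
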