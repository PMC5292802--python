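"""Tabular file formats for HLA case-control analysis.

Reads and writes the three text formats the toolkit consumes — the genotype
table (one row per individual: sample ID, phenotype, two allele columns per
locus), the covariate table, and the expanded amino-acid alignment — and
normalises HLA allele names to a canonical ``GENE*f1:f2:...`` form with
explicit control over typing resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("hlassoc")

#: Tokens that denote a missing allele call in genotype files.
MISSING_TOKENS = frozenset({"NA", "0", "-", ""})

#: Binary phenotype coding: 1 = control, 2 = case; anything else = excluded.
CONTROL_CODE = 1
CASE_CODE = 2

#: Residue alphabet of an amino-acid alignment column.
AA_UNKNOWN = "*"
AA_INDEL = "-"


class ParseError(ValueError):
    """A malformed token or row in one of the input files."""


# ---------------------------------------------------------------------------
# Allele names
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele identifier, e.g. ``A*01:01``.

    Parameters
    ----------
    gene
        Locus symbol (``A``, ``B``, ``DQB1`` ...). Compared case-insensitively.
    fields
        Colon-separated resolution fields, highest level first. One field is
        the antigen ("two-digit") level, two fields the protein ("four-digit")
        level.
    raw
        The original string as read from the file, kept for error messages.
    """

    gene: str
    fields: tuple[str, ...]
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.gene or not self.fields:
            raise ParseError(f"invalid allele name {self.raw!r}")

    def __str__(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self.gene.upper() == other.gene.upper() and self.fields == other.fields

    def __hash__(self) -> int:
        return hash((self.gene.upper(), self.fields))

    @property
    def resolution(self) -> int:
        """Number of name fields (1 = two-digit, 2 = four-digit, ...)."""
        return len(self.fields)


def parse_allele_name(raw: str) -> AlleleName:
    """Parse an allele string such as ``HLA-A*01:01`` or ``DQB1*05:02``.

    A leading ``HLA-`` prefix is stripped. Raises :class:`ParseError` when the
    ``*`` separator is absent or any colon field is empty.
    """
    if not raw:
        raise ParseError("empty allele name")
    s = raw.strip()
    body = s[4:] if s.upper().startswith("HLA-") else s
    if "*" not in body:
        raise ParseError(f"allele name {raw!r} lacks the '*' gene/field separator")
    gene, _, rest = body.partition("*")
    fields = tuple(rest.split(":"))
    if not gene or any(f == "" for f in fields):
        raise ParseError(f"allele name {raw!r} has an empty gene or field")
    return AlleleName(gene=gene, fields=fields, raw=s)


def truncate_resolution(a: AlleleName, n_fields: int) -> AlleleName:
    """Truncate an allele to its first ``n_fields`` name fields.

    Truncation is a prefix operation and idempotent: an allele already at or
    below the requested resolution is returned unchanged.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if len(a.fields) <= n_fields:
        return a
    return AlleleName(gene=a.gene, fields=a.fields[:n_fields], raw=a.raw)


def digits_to_fields(digits: int) -> int:
    """Map the CLI's ``--digits {2,4,6,8}`` vocabulary to a field count."""
    mapping = {2: 1, 4: 2, 6: 3, 8: 4}
    if digits not in mapping:
        raise ValueError(f"digits must be one of {sorted(mapping)}, got {digits}")
    return mapping[digits]


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

Call = tuple[AlleleName, AlleleName]


@dataclass
class GenotypeTable:
    """Individuals x loci genotype matrix with a phenotype vector.

    ``calls[i][j]`` holds the unordered allele pair of sample ``i`` at locus
    ``j`` or ``None`` for a missing call. For binary traits ``phenotype``
    holds 1 (control) / 2 (case); for quantitative traits, finite reals.
    """

    samples: list[str]
    phenotype: list[float]
    loci: list[str]
    calls: list[list[Call | None]]
    trait_type: str = "binary"  # "binary" | "quantitative"

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = {s for s in self.samples if self.samples.count(s) > 1}
            raise ParseError(f"duplicate sample IDs: {sorted(dupes)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_case(self, i: int) -> bool:
        return self.trait_type == "binary" and self.phenotype[i] == CASE_CODE

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in table (have {self.loci})") from None

    def typed_indices(self, locus: str) -> list[int]:
        """Indices of individuals with a non-missing call at ``locus``."""
        j = self.locus_index(locus)
        return [i for i in range(self.n_samples) if self.calls[i][j] is not None]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_genotype_table(
    path: str | Path,
    trait_type: str = "binary",
    loci: Sequence[str] | None = None,
) -> GenotypeTable:
    """Read a whitespace/tab-delimited genotype file.

    Layout: column 1 = sample ID, column 2 = phenotype, then two allele
    columns per locus. An optional header row is detected when its phenotype
    column is non-numeric; when present and ``loci`` is not given, locus
    names are taken from the header's odd allele columns' gene prefix.
    Binary phenotypes use 1 = control / 2 = case; individuals with any other
    value are excluded with a warning.
    """
    if trait_type not in ("binary", "quantitative"):
        raise ValueError(f"unknown trait_type {trait_type!r}")
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    # Header detection: phenotype column of row 1 must be numeric for data.
    start = 1 if not _is_number(lines[0][1]) else 0
    rows = lines[start:]
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncol = len(rows[0])
    if ncol < 4 or (ncol - 2) % 2 != 0:
        raise ParseError(
            f"{path}: expected 2 + 2*loci columns, got {ncol} in first data row"
        )
    n_loci = (ncol - 2) // 2

    samples: list[str] = []
    phenotype: list[float] = []
    calls: list[list[Call | None]] = []
    inferred_loci: list[str] | None = list(loci) if loci is not None else None

    for r, row in enumerate(rows, start=start + 1):
        if len(row) != ncol:
            raise ParseError(f"{path}: row {r} has {len(row)} columns, expected {ncol}")
        sid, pheno_tok = row[0], row[1]
        if sid in samples:
            raise ParseError(f"{path}: duplicate sample ID {sid!r} (row {r})")
        if not _is_number(pheno_tok):
            raise ParseError(f"{path}: non-numeric phenotype {pheno_tok!r} (row {r})")
        pheno = float(pheno_tok)
        if trait_type == "binary" and pheno not in (CONTROL_CODE, CASE_CODE):
            logger.warning(
                "%s: sample %s has phenotype %s (not 1/2); excluded", path, sid, pheno_tok
            )
            continue
        row_calls: list[Call | None] = []
        for k in range(n_loci):
            a_tok, b_tok = row[2 + 2 * k], row[3 + 2 * k]
            if a_tok in MISSING_TOKENS or b_tok in MISSING_TOKENS:
                row_calls.append(None)
                continue
            a, b = parse_allele_name(a_tok), parse_allele_name(b_tok)
            if a.gene.upper() != b.gene.upper():
                raise ParseError(
                    f"{path}: row {r}, locus column {k + 1}: allele pair "
                    f"{a_tok}/{b_tok} spans two genes"
                )
            row_calls.append((a, b))
        samples.append(sid)
        phenotype.append(pheno)
        calls.append(row_calls)

    if inferred_loci is None:
        inferred_loci = _infer_loci(calls, n_loci, path)
    if len(inferred_loci) != n_loci:
        raise ParseError(
            f"{path}: {len(inferred_loci)} locus names for {n_loci} column pairs"
        )
    # Per-call gene must match its declared locus.
    for i, row_calls in enumerate(calls):
        for j, call in enumerate(row_calls):
            if call is not None and call[0].gene.upper() != inferred_loci[j].upper():
                raise ParseError(
                    f"{path}: sample {samples[i]} has {call[0]} in the "
                    f"{inferred_loci[j]} column"
                )
    return GenotypeTable(samples, phenotype, inferred_loci, calls, trait_type)


def _infer_loci(
    calls: list[list[Call | None]], n_loci: int, path: str | Path
) -> list[str]:
    names: list[str] = []
    for j in range(n_loci):
        gene = next(
            (row[j][0].gene for row in calls if row[j] is not None), None
        )
        if gene is None:
            raise ParseError(f"{path}: locus column {j + 1} has no typed call")
        names.append(gene)
    return names


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table in the format :func:`read_genotype_table` reads.

    Missing calls are written as ``NA NA``. Phenotypes that are whole numbers
    are written without a decimal point so binary files round-trip exactly.
    """
    lines = []
    for i, sid in enumerate(table.samples):
        p = table.phenotype[i]
        pheno = str(int(p)) if float(p).is_integer() else repr(p)
        toks = [sid, pheno]
        for call in table.calls[i]:
            toks.extend(("NA", "NA") if call is None else (str(call[0]), str(call[1])))
        lines.append(" ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Real-valued covariates keyed by sample ID (binary ones coded 0/1)."""

    names: list[str]
    values: dict[str, list[float]]

    def __post_init__(self) -> None:
        k = len(self.names)
        for sid, vec in self.values.items():
            if len(vec) != k:
                raise ParseError(
                    f"sample {sid!r}: {len(vec)} covariates, expected {k}"
                )

    def matrix(self, samples: Sequence[str]):
        """Covariate rows aligned to ``samples`` as a DataFrame."""
        return pd.DataFrame(
            [self.values[s] for s in samples], index=list(samples), columns=self.names
        )


def read_covariates(path: str | Path, samples: Sequence[str]) -> CovariateTable:
    """Read a delimited covariate file (column 1 = sample ID, rest = covariates).

    The first row is a header naming the covariates when its second column is
    non-numeric; otherwise covariates are named ``cov1..covk``. Samples absent
    from the file are flagged with a warning; callers exclude them from
    regression.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty covariate file")
    if len(lines[0]) < 2:
        raise ParseError(f"{path}: covariate file needs >= 2 columns")
    if not _is_number(lines[0][1]):
        names = lines[0][1:]
        rows = lines[1:]
    else:
        names = [f"cov{i + 1}" for i in range(len(lines[0]) - 1)]
        rows = lines
    values: dict[str, list[float]] = {}
    for r, row in enumerate(rows, start=1):
        sid = row[0]
        vec = []
        for c, tok in enumerate(row[1:], start=2):
            if not _is_number(tok):
                raise ParseError(
                    f"{path}: non-numeric covariate {tok!r} at row {r}, column {c}"
                )
            vec.append(float(tok))
        values[sid] = vec
    missing = [s for s in samples if s not in values]
    if missing:
        logger.warning(
            "%s: %d sample(s) absent from covariate file (e.g. %s); they are "
            "excluded from regression", path, len(missing), missing[:5],
        )
    return CovariateTable(names=names, values=values)


# ---------------------------------------------------------------------------
# Amino-acid alignment
# ---------------------------------------------------------------------------

@dataclass
class AAAlignment:
    """Equal-length aligned protein sequences for the alleles of one gene.

    Positions are 1-based alignment columns as given in the input file; no
    renumbering to the mature protein is applied. ``-`` is an indel state and
    ``*`` an unknown residue.
    """

    gene: str
    sequences: dict[AlleleName, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def resolution(self) -> int:
        """Field count the alignment's allele names are stated at."""
        return min(a.resolution for a in self.sequences)

    def residue(self, allele: AlleleName, position: int) -> str | None:
        """Residue of ``allele`` at 1-based ``position``; None if allele absent.

        The query allele is truncated to the alignment's resolution first.
        """
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside [1, {self.length}] for gene {self.gene}"
            )
        seq = self.sequences.get(truncate_resolution(allele, self.resolution))
        return None if seq is None else seq[position - 1]


def read_aa_alignment(path: str | Path) -> dict[str, AAAlignment]:
    """Read the expanded alignment format: one row = gene, allele, sequence.

    Every row spells out its full residue string (the IMGT identity-dash
    dialect is deliberately not supported; see docs for conversion). Within a
    gene all sequences must have equal length. Duplicate rows with identical
    sequences are deduplicated with a warning; conflicting duplicates are an
    error.
    """
    alignments: dict[str, AAAlignment] = {}
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    for r, row in enumerate(lines, start=1):
        if len(row) != 3:
            raise ParseError(f"{path}: row {r} needs 3 columns (gene allele sequence)")
        gene, allele_tok, seq = row
        allele = parse_allele_name(allele_tok)
        aln = alignments.setdefault(gene, AAAlignment(gene=gene))
        if aln.sequences and len(seq) != aln.length:
            raise ParseError(
                f"{path}: allele {allele} has sequence length {len(seq)}, "
                f"expected {aln.length} for gene {gene}"
            )
        if allele in aln.sequences:
            if aln.sequences[allele] != seq:
                raise ParseError(
                    f"{path}: allele {allele} listed twice with different sequences"
                )
            logger.warning("%s: duplicate row for allele %s; deduplicated", path, allele)
            continue
        aln.sequences[allele] = seq
    if not alignments:
        raise ParseError(f"{path}: empty alignment file")
    return alignments


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

#: Column order of the TSV/text report. Absent values render as empty cells.
REPORT_COLUMNS = [
    "label", "method", "a", "b", "c", "d",
    "statistic", "p_value", "p_adjusted", "effect", "effect_se",
    "ci_low", "ci_high", "note",
]


def results_frame(results: Iterable) -> pd.DataFrame:
    """Flatten TestResult objects into the report DataFrame."""
    rows = []
    for res in results:
        t = getattr(res, "table", None)
        rows.append({
            "label": res.label,
            "method": res.method,
            "a": t.counts[0][0] if t is not None else None,
            "b": t.counts[0][1] if t is not None else None,
            "c": t.counts[1][0] if t is not None else None,
            "d": t.counts[1][1] if t is not None else None,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "p_adjusted": res.p_adjusted,
            "effect": res.effect,
            "effect_se": res.effect_se,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "note": res.note or "",
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(results: Iterable, path: str | Path, format: str = "tsv") -> None:
    """Write test results as TSV (full precision) or aligned text.

    Row order is the order of ``results`` (callers sort deterministically);
    the same results always produce byte-identical files.
    """
    df = results_frame(results)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")
    elif format == "text":
        def _fmt(v):
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return ""
            if isinstance(v, float):
                return f"{v:.3E}"
            return str(v)
        shown = df.map(_fmt)
        Path(path).write_text(shown.to_string(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
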