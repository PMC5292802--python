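"""Testable factors: an HLA allele, or a residue at an alignment position.

Both the zygosity and the interaction modules classify individuals by how
many gene copies carry a factor. An :class:`AlleleFactor` counts copies of
one allele at a locus; a :class:`ResidueFactor` counts gene copies whose
allele codes for a given residue at a 1-based alignment column. Individuals
whose carriage cannot be determined (missing call, allele absent from the
alignment, unknown '*' residue) are excluded with copies() returning None.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AAAlignment, AlleleName, AA_UNKNOWN, parse_allele_name
from .association import copies_of


@dataclass(frozen=True)
class AlleleFactor:
    locus: str
    allele: AlleleName
    digits_fields: int = 2

    def __str__(self) -> str:
        return f"{self.locus}:{self.allele}"

    def copies(self, call) -> int | None:
        if call is None:
            return None
        return copies_of(call, self.allele, self.digits_fields)


@dataclass(frozen=True)
class ResidueFactor:
    gene: str
    position: int  # 1-based alignment column
    residue: str

    def __str__(self) -> str:
        return f"{self.gene}:pos{self.position}:{self.residue}"

    def copies(self, call, aln: AAAlignment) -> int | None:
        if call is None:
            return None
        residues = [aln.residue(a, self.position) for a in call]
        if any(r is None or r == AA_UNKNOWN for r in residues):
            return None
        return sum(1 for r in residues if r == self.residue)


def parse_factor(text: str) -> AlleleFactor | ResidueFactor:
    """Parse a CLI factor string: ``A*01:01`` or ``DRB1:pos71:K``.

    An allele string names its locus via the gene prefix; a residue factor is
    ``GENE:pos<column>:<residue>``.
    """
    parts = text.split(":")
    if len(parts) == 3 and parts[1].startswith("pos"):
        gene, pos_tok, residue = parts
        try:
            position = int(pos_tok[3:])
        except ValueError:
            raise ValueError(f"bad position in factor {text!r}") from None
        if len(residue) != 1:
            raise ValueError(f"residue in factor {text!r} must be one character")
        return ResidueFactor(gene=gene, position=position, residue=residue)
    allele = parse_allele_name(text)
    return AlleleFactor(
        locus=allele.gene, allele=allele, digits_fields=len(allele.fields)
    )
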