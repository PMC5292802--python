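import pytest
from hypothesis import settings

from hlassoc import AAAlignment, GenotypeTable, parse_allele_name

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_table(rows, loci, trait_type="binary"):
    """Build a GenotypeTable from (sample, phenotype, allele-pair-strings) rows.

    Each row is (sid, pheno, [(a1, a2) or None per locus]).
    """
    samples, phenos, calls = [], [], []
    for sid, pheno, row_calls in rows:
        samples.append(sid)
        phenos.append(float(pheno))
        calls.append([
            None if c is None
            else (parse_allele_name(c[0]), parse_allele_name(c[1]))
            for c in row_calls
        ])
    return GenotypeTable(samples, phenos, list(loci), calls, trait_type)


@pytest.fixture
def toy_table():
    """One locus, 4 cases / 4 controls with an enriched A*01:01 in cases."""
    rows = [
        ("C1", 2, [("A*01:01", "A*01:01")]),
        ("C2", 2, [("A*01:01", "A*02:01")]),
        ("C3", 2, [("A*01:01", "A*02:01")]),
        ("C4", 2, [("A*02:01", "A*03:01")]),
        ("K1", 1, [("A*02:01", "A*02:01")]),
        ("K2", 1, [("A*02:01", "A*03:01")]),
        ("K3", 1, [("A*01:01", "A*03:01")]),
        ("K4", 1, [("A*03:01", "A*03:01")]),
    ]
    return make_table(rows, ["A"])


@pytest.fixture
def toy_alignment():
    """Three A alleles whose residues at position 2 separate A*01:01."""
    aln = AAAlignment(gene="A")
    aln.sequences = {
        parse_allele_name("A*01:01"): "MAVM",
        parse_allele_name("A*02:01"): "MTVM",
        parse_allele_name("A*03:01"): "MTVL",
    }
    return aln
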