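# Methods

## Input model

An individual is a sample ID, a phenotype, and an unordered allele pair per
HLA locus. Binary phenotypes are coded 1 = control, 2 = case — the dominant
convention in genetics tooling — and any other value excludes the individual
with a logged warning. The missing-allele tokens `NA`, `0`, `-` and the
empty field are equivalent; an individual missing *either* allele at a locus
is excluded from every analysis at that locus (only). Allele names follow
the colon-delimited nomenclature (`A*01:01`, optional `HLA-` prefix
stripped); genes compare case-insensitively, fields exactly. Resolution is
expressed in name fields: 1 field = "two-digit"/antigen level, 2 fields =
"four-digit"/protein level; the CLI's `--digits {2,4,6,8}` maps to 1–4
fields, and alleles are truncated (a pure prefix operation) before any
counting.

## 2×2 tests

The Pearson χ² statistic Σ(O−E)²/E is referred to the upper tail of χ²₁ with
**no Yates continuity correction**; a zero margin is a degenerate-table
error (batch runs flag the result and continue; Fisher remains defined
there). The two-sided Fisher exact p sums hypergeometric probabilities of
all same-margin tables whose probability does not exceed the observed
table's, with a relative tie tolerance of 1e-7 so float round-off cannot
drop an exactly tied table — the convention used by the major statistical
packages, which the test suite cross-checks against both exact integer
enumeration and an independent library implementation. Odds ratios are
ad/bc; when any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe) before the ratio and the Wald interval
exp(log OR ± 1.96·√Σ1/cell).

## Per-allele scan

At a locus with *n* observed alleles, each allele with combined gene-copy
count ≥ `min_count` (default 5, a conventional floor for χ² validity — the
field's notion of a "common allele" rarely comes with a stated number) is tested
against the other alleles grouped together. Rare alleles are *pooled into
the "other" side* rather than dropped, so column totals remain 2 × typed
individuals. In the allelic construction an individual contributes both gene
copies with no within-individual correlation adjustment — that is the
classical definition of the allelic 2×2 and is exact under
Hardy–Weinberg-style independence of the two copies; the simulator draws
copies independently, so the calibration tests exercise exactly the regime
where the construction is valid. Regression uses the additive (copy count),
dominant (≥1 copy) or recessive (2 copies) 0/1/2 code of the tested allele;
the tested allele is always the effect allele — no minor-allele
re-polarisation. Logistic fits are maximum likelihood with Wald per-
coefficient p-values; separation, rank deficiency, constant outcome or
non-convergence produce a flagged result (p = 1, note set), never a crash.

The multiple-testing family is all tests of one run, across loci — the most
conservative commonly used choice. Benjamini–Hochberg is the FDR estimator
(step-up, monotonised, capped at 1). Permutation p-values shuffle the
phenotype vector (Fisher–Yates via one seeded generator) while genotypes
stay fixed, apply the *same* shuffles to every test so the correlation
structure among alleles is preserved, measure extremeness on the p-value
scale (permuted p ≤ observed p) so χ², Fisher and regression share one
engine, and use the add-one estimator (b+1)/(B+1), which cannot return 0.
Because permuted p *ties* count as extreme, the empirical p is slightly
conservative for strongly discrete tables (small samples); the calibration
test uses 500+500 individuals, where the tie mass is small.

## Amino-acid level

The alignment file is deliberately simple: one row per allele — gene, allele
name, fully expanded aligned sequence over the 20 amino-acid letters plus
`-` (indel) and `*` (unknown). The IMGT/HLA release alignments use an
identity-dash dialect (a reference sequence plus `-` meaning "same as
reference"); convert by replacing each dash with the reference residue at
that column and writing every sequence in full, one per line. Positions are
1-based alignment columns exactly as in the file — no renumbering to the
mature protein, which avoids silent offset bugs; users who want mature-
protein coordinates should number their alignment accordingly.

Genotype alleles are truncated to the alignment's resolution before lookup.
An individual whose allele is absent from the alignment is excluded at that
gene with a warning. The indel state `-` is an ordinary, testable residue
class (indel presence can itself associate); `*` is unknown and excluded —
per gene copy in the allelic construction, per individual in the carrier
constructions (a carrier state cannot be decided when one copy is unknown).
A column where only one residue class is observed yields no test.

## Zygosity tests

For a factor (allele, or residue at a position) every typed individual is
homozygous, heterozygous or absent; the three states partition the sample.
The three tables are homozygous-vs-absent, heterozygous-vs-absent, and
homozygous-vs-heterozygous (carriers only). This three-way layout is an
interpretation of the classical "homozygous, heterozygous and zygosity
association" triple: the first two ask whether each carrier state is
individually associated with disease, the third whether susceptibility
differs *between* carrier states. The dominant-model table of the per-allele
scan equals the element-wise (hom+het)-vs-absent collapse of these counts —
a cross-module identity the test suite asserts.

## Interaction battery

Two factors A and B, positivity = carriage (≥ 1 copy), give the eight-fold
counts a–d (cases) and e–h (controls). The eight tables follow the classical
two-antigen decomposition: T1/T2 marginal association of each factor; T3/T4
association of A within B-positive and B-negative strata (and T5/T6 for B
within A strata) — jointly reading out differential and combined action;
T7/T8 association *between* the factors within cases and within controls —
linkage disequilibrium on each side. T3+T4 reproduce T1 cell-wise and T5+T6
reproduce T2, a conservation property the suite asserts. The battery is
purely 2×2; model-based (product-term) interaction is out of scope.

## Simulator

Genotypes are two independent gene copies per locus from configured allele
frequencies. One designated allele pair at two loci can be placed in LD by
drawing the pair's carriage indicators per haplotype from a joint
distribution with P(A∧B) = p_A·p_B + D; D outside the Fréchet bounds
[max(−p_Ap_B, −(1−p_A)(1−p_B)), min(p_A(1−p_B), (1−p_A)p_B)] is rejected
with the admissible range in the message. Binary disease follows
logit Pr(case) = β₀ + Σ log(OR)·code; case/control quotas are filled by
rejection sampling so fixtures have exact sizes (a deliberate design choice
over prevalence-based sampling). β₀ defaults to logit(0.5): under
retrospective case-control sampling the slope estimate is unaffected by the
intercept, and a balanced baseline keeps quota sampling efficient.
Quantitative traits are y = β₀ + Σ shift·code + ε with Gaussian ε.

What the simulator does *not* emulate: within-individual copy correlation
(Hardy–Weinberg disequilibrium), population stratification, genotyping or
imputation error, multi-locus haplotype structure beyond the single LD pair,
and covariate-trait confounding. Passing calibration and recovery tests
therefore demonstrate correctness of the statistical machinery under an
idealised exchangeable design, not robustness to those real-data features.

## Default study sizes in tests and the acceptance script

Null calibration uses 200+200 individuals × 2,000 replicates (χ²) and
500+500 × 500 replicates (interaction battery); logistic recovery averages
50 studies of 1,000+1,000; linear recovery uses one study of n = 2,000; the
demonstration analysis is 1,000 cases + 1,000 controls. These sizes give
binomial standard errors comfortably inside the asserted bands while keeping
a full run to seconds.

## Known limitations

* Case-control and quantitative designs only; no family-based tests.
* No haplotype frequency estimation, Hardy–Weinberg testing, or omnibus
  (locus-wide, df = n−1) tests — the method is the per-factor 2×2
  decomposition.
* Fisher mid-p variants, exact OR confidence intervals and max-T
  (Westfall–Young) permutation are not implemented; permutation p-values
  are pointwise.
* Amino-acid analysis tests single positions; epitope (multi-residue) and
  conditional/stepwise analyses are out of scope.
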