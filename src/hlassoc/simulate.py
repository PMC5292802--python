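"""Seeded generator of case-control and quantitative HLA datasets.

Genotypes are drawn as two independent gene copies per individual from
configured per-locus allele frequencies; one designated allele pair at two
loci may be placed in linkage disequilibrium by drawing their haplotype
indicators from a joint distribution with a requested disequilibrium
coefficient D (P(A and B on one haplotype) = pA*pB + D, D inside the
Frechet bounds). Binary phenotypes follow a logistic disease model whose
slope on the 0/1/2 genotype code is log(OR); case and control quotas are
filled by rejection sampling so fixtures have exact sizes. Quantitative
phenotypes follow a linear model with Gaussian noise. Everything is
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import AlleleName, GenotypeTable, parse_allele_name


@dataclass(frozen=True)
class RiskAllele:
    """One disease-associated allele and its effect.

    For binary traits ``effect`` is the per-code odds ratio (slope exp);
    for quantitative traits it is the per-code mean shift in trait units.
    """

    locus: str
    allele: str
    model: str = "additive"  # additive | dominant | recessive
    effect: float = 1.0

    def code(self, copies: np.ndarray) -> np.ndarray:
        if self.model == "additive":
            return copies
        if self.model == "dominant":
            return (copies >= 1).astype(int)
        if self.model == "recessive":
            return (copies == 2).astype(int)
        raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class LDPair:
    """Haplotype-level disequilibrium D between two designated alleles."""

    locus_a: str
    allele_a: str
    locus_b: str
    allele_b: str
    d: float


@dataclass
class SimConfig:
    """Study design of one simulated dataset.

    ``loci`` maps each gene to its population allele frequencies (must sum
    to 1). ``base_prevalence`` sets the logistic intercept; under
    case-control (retrospective) sampling the slope estimate is unaffected
    by it, so the default 0.5 simply keeps quota sampling efficient.
    """

    loci: dict[str, dict[str, float]]
    n_case: int = 0
    n_control: int = 0
    n: int = 0  # quantitative designs
    trait_type: str = "binary"
    risk: list[RiskAllele] = field(default_factory=list)
    ld: LDPair | None = None
    base_prevalence: float = 0.5
    intercept: float = 0.0       # quantitative beta0
    noise_sd: float = 1.0        # quantitative residual sd
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, freqs in self.loci.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene}: allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{gene}: negative allele frequency")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        for r in self.risk:
            if r.effect <= 0 and self.trait_type == "binary":
                raise ValueError("odds ratio must be > 0")
        if self.ld is not None:
            lo, hi = frechet_bounds(
                self.loci[self.ld.locus_a][self.ld.allele_a],
                self.loci[self.ld.locus_b][self.ld.allele_b],
            )
            if not lo <= self.ld.d <= hi:
                raise ValueError(
                    f"LD coefficient {self.ld.d} outside the admissible range "
                    f"[{lo:.6g}, {hi:.6g}] for these allele frequencies"
                )


def frechet_bounds(p_a: float, p_b: float) -> tuple[float, float]:
    """Admissible range of the haplotype disequilibrium D for frequencies
    p_a, p_b: max(-pa*pb, -(1-pa)(1-pb)) <= D <= min(pa(1-pb), (1-pa)pb)."""
    return (
        max(-p_a * p_b, -(1 - p_a) * (1 - p_b)),
        min(p_a * (1 - p_b), (1 - p_a) * p_b),
    )


def _draw_haplotypes(
    config: SimConfig, n_hap: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per locus, an integer allele index per haplotype (gene copy)."""
    allele_lists = {g: sorted(f) for g, f in config.loci.items()}
    out: dict[str, np.ndarray] = {}
    ld = config.ld
    ld_loci = {ld.locus_a, ld.locus_b} if ld else set()
    for gene, alleles in allele_lists.items():
        if gene not in ld_loci:
            p = np.array([config.loci[gene][a] for a in alleles])
            out[gene] = rng.choice(len(alleles), size=n_hap, p=p)
    if ld:
        pa = config.loci[ld.locus_a][ld.allele_a]
        pb = config.loci[ld.locus_b][ld.allele_b]
        p11 = pa * pb + ld.d
        # joint carriage indicators for the designated pair on one haplotype
        probs = np.array([p11, pa - p11, pb - p11, 1 - pa - pb + p11])
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        joint = rng.choice(4, size=n_hap, p=probs)
        ia = (joint == 0) | (joint == 1)
        ib = (joint == 0) | (joint == 2)
        for gene, target_allele, ind in (
            (ld.locus_a, ld.allele_a, ia),
            (ld.locus_b, ld.allele_b, ib),
        ):
            alleles = allele_lists[gene]
            target = alleles.index(target_allele)
            others = [k for k in range(len(alleles)) if k != target]
            p_others = np.array([config.loci[gene][alleles[k]] for k in others])
            p_others = p_others / p_others.sum()
            draw = np.full(n_hap, target)
            n_other = int((~ind).sum())
            if n_other and others:
                draw[~ind] = np.array(others)[rng.choice(len(others), size=n_other,
                                                         p=p_others)]
            out[gene] = draw
    return out


def _risk_score(
    config: SimConfig, hap1: dict[str, np.ndarray], hap2: dict[str, np.ndarray],
    allele_lists: dict[str, list[str]],
) -> np.ndarray:
    """Sum of slope * genotype-code over the configured risk alleles."""
    n = len(next(iter(hap1.values()))) if hap1 else 0
    score = np.zeros(n)
    for r in config.risk:
        alleles = allele_lists[r.locus]
        idx = alleles.index(r.allele)
        copies = (hap1[r.locus] == idx).astype(int) + (hap2[r.locus] == idx).astype(int)
        slope = np.log(r.effect) if config.trait_type == "binary" else r.effect
        score += slope * r.code(copies)
    return score


def simulate(config: SimConfig) -> tuple[GenotypeTable, dict]:
    """Draw a genotype table and return it with the true-parameter record."""
    rng = np.random.default_rng(config.seed)
    allele_lists = {g: sorted(f) for g, f in config.loci.items()}
    loci = list(config.loci)
    parsed = {
        g: [parse_allele_name(f"{g}*{a}" if "*" not in a else a)
            for a in allele_lists[g]]
        for g in loci
    }

    def make_rows(n_draw: int):
        h1 = _draw_haplotypes(config, n_draw, rng)
        h2 = _draw_haplotypes(config, n_draw, rng)
        score = _risk_score(config, h1, h2, allele_lists)
        return h1, h2, score

    kept_h1: dict[str, list[int]] = {g: [] for g in loci}
    kept_h2: dict[str, list[int]] = {g: [] for g in loci}
    phenotype: list[float] = []

    if config.trait_type == "binary":
        if config.n_case < 1 or config.n_control < 1:
            raise ValueError("binary design needs n_case and n_control >= 1")
        beta0 = float(np.log(config.base_prevalence / (1 - config.base_prevalence)))
        need_case, need_control = config.n_case, config.n_control
        while need_case > 0 or need_control > 0:
            batch = max(64, 2 * (need_case + need_control))
            h1, h2, score = make_rows(batch)
            prob = 1 / (1 + np.exp(-(beta0 + score)))
            is_case = rng.random(batch) < prob
            for i in range(batch):
                if is_case[i] and need_case > 0:
                    need_case -= 1
                elif not is_case[i] and need_control > 0:
                    need_control -= 1
                else:
                    continue
                phenotype.append(2.0 if is_case[i] else 1.0)
                for g in loci:
                    kept_h1[g].append(int(h1[g][i]))
                    kept_h2[g].append(int(h2[g][i]))
    else:
        if config.n < 1:
            raise ValueError("quantitative design needs n >= 1")
        h1, h2, score = make_rows(config.n)
        y = config.intercept + score + rng.normal(0, config.noise_sd, config.n)
        phenotype = y.tolist()
        for g in loci:
            kept_h1[g] = h1[g].tolist()
            kept_h2[g] = h2[g].tolist()

    n_total = len(phenotype)
    calls: list[list[tuple[AlleleName, AlleleName] | None]] = []
    miss = (
        rng.random((n_total, len(loci))) < config.missingness
        if config.missingness > 0 else np.zeros((n_total, len(loci)), dtype=bool)
    )
    for i in range(n_total):
        row = []
        for j, g in enumerate(loci):
            if miss[i, j]:
                row.append(None)
            else:
                row.append((parsed[g][kept_h1[g][i]], parsed[g][kept_h2[g][i]]))
        calls.append(row)

    samples = [f"S{i + 1}" for i in range(n_total)]
    table = GenotypeTable(samples, phenotype, loci, calls, config.trait_type)
    truth = {
        "seed": config.seed,
        "trait_type": config.trait_type,
        "loci": {g: dict(config.loci[g]) for g in loci},
        "risk": [
            {"locus": r.locus, "allele": r.allele, "model": r.model,
             "effect": r.effect}
            for r in config.risk
        ],
        "ld": None if config.ld is None else {
            "locus_a": config.ld.locus_a, "allele_a": config.ld.allele_a,
            "locus_b": config.ld.locus_b, "allele_b": config.ld.allele_b,
            "d": config.ld.d,
        },
        "n_case": config.n_case, "n_control": config.n_control, "n": config.n,
        "base_prevalence": config.base_prevalence,
        "intercept": config.intercept, "noise_sd": config.noise_sd,
        "missingness": config.missingness,
    }
    return table, truth


def write_true_params(truth: dict, path: str | Path) -> None:
    """Sidecar JSON with the generating parameters, for recovery tests."""
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
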