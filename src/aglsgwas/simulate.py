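"""Synthetic cohorts with the statistical structure the AGLS scan assumes.

The generator emulates, at desk scale, the ingredients of a dairy-cattle
GWAS cohort: biallelic SNP genotypes with configurable allele frequencies
and inbreeding-style Hardy-Weinberg disequilibrium; per-trait polygenic
values built from many small background-locus effects (or, optionally, a
multivariate normal with an explicit relationship matrix for oracle tests);
PTAs correlated with the true polygenic value at a stated reliability; and
planted per-SNP effects parameterized directly by the average effect of
gene substitution (alpha) and the dominance effect (delta), including
antagonistic pleiotropy (opposite-sign alpha on two traits).

Defaults describe a moderately heritable production-like trait (h^2 = 0.3
on a unit phenotypic scale) with PTA reliability 0.8, in a cohort of 5,000
individuals and 2,000 SNPs with allele frequencies uniform on (0.05, 0.95).

Everything is driven by one named generator (numpy PCG64 via
``default_rng(seed)``), so a fixed seed reproduces the dataset and its truth
record bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeMatrix, PhenotypeTable, PtaTable, SnpRecord
from .freq import additive_contrast, genotype_frequencies


@dataclass(frozen=True)
class TraitSpec:
    """Variance components and PTA quality for one simulated trait."""

    sigma_a2: float = 0.3        # additive polygenic variance
    sigma_e2: float = 0.7        # residual variance
    pta_reliability: float = 0.8  # squared correlation of 2*PTA with a

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 <= self.pta_reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")


@dataclass(frozen=True)
class CausalEffect:
    """One planted SNP effect: alpha/delta on one trait, in trait units."""

    snp_index: int
    trait: str
    alpha: float
    delta: float = 0.0


@dataclass
class SimulationConfig:
    n_individuals: int = 5000
    n_snps: int = 2000
    freq_range: tuple[float, float] = (0.05, 0.95)  # sampler for allele1 freq
    fixed_p1: float | None = None                   # overrides the sampler
    inbreeding_f: float = 0.0                       # HWD control, 0 <= f < 1
    causal: list[CausalEffect] = field(default_factory=list)
    traits: dict[str, TraitSpec] = field(
        default_factory=lambda: {"trait1": TraitSpec()}
    )
    n_background_loci: int = 200
    mu: float = 0.0
    a_mode: str = "loci"             # "loci" | "mvn"
    relationship_matrix: np.ndarray | None = None   # required for a_mode="mvn"
    ld_copies: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding_f must be in [0, 1)")
        for c in self.causal:
            if not 0 <= c.snp_index < self.n_snps:
                raise ValueError(f"causal snp_index {c.snp_index} out of range")
            if c.trait not in self.traits:
                raise ValueError(f"causal trait {c.trait!r} not in trait spec")


@dataclass
class TruthRecord:
    """Everything needed to recompute the phenotypes given the seed."""

    a_by_trait: dict[str, np.ndarray]        # true polygenic values
    e_by_trait: dict[str, np.ndarray]        # residuals
    causal_values: dict[tuple[str, str], tuple[float, float, float]]
    realized_freqs: dict[str, tuple[float, float]]
    requested: list[CausalEffect]


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    pta: PtaTable
    truth: TruthRecord
    config: SimulationConfig


def _hwd_probs(p1: np.ndarray, f: float) -> np.ndarray:
    """Genotype probabilities (P11, P12, P22) with inbreeding coefficient f."""
    p2 = 1.0 - p1
    return np.stack(
        [p1 * p1 + f * p1 * p2, 2.0 * p1 * p2 * (1.0 - f), p2 * p2 + f * p1 * p2],
        axis=-1,
    )


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw a genotype matrix; SNPs independent unless ``ld_copies`` is set."""
    rng = rng or np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    if config.fixed_p1 is not None:
        p1 = np.full(m, float(config.fixed_p1))
    else:
        lo, hi = config.freq_range
        p1 = rng.uniform(lo, hi, size=m)
    probs = _hwd_probs(p1, config.inbreeding_f)
    u = rng.random((n, m))
    codes = (
        (u > probs[:, 0]).astype(np.int8) + (u > probs[:, 0] + probs[:, 1]).astype(np.int8)
    )
    for src, dst, noise in config.ld_copies:
        codes[:, dst] = codes[:, src]
        if noise > 0.0:
            hit = rng.random(n) < noise
            k = int(hit.sum())
            if k:
                u2 = rng.random(k)
                codes[hit, dst] = (
                    (u2 > probs[dst, 0]).astype(np.int8)
                    + (u2 > probs[dst, 0] + probs[dst, 1]).astype(np.int8)
                )
    individuals = [f"id{i + 1}" for i in range(n)]
    snps = [
        SnpRecord(f"snp{j + 1:05d}", "1", 1 + 1000 * j, "A", "B") for j in range(m)
    ]
    return GenotypeMatrix(individuals, snps, codes)


def causal_class_values(
    column: np.ndarray, alpha: float, delta: float
) -> tuple[float, float, float]:
    """Genotypic class values realizing the requested (alpha, delta).

    Solves for x in g = x*(-2 p2, p1 - p2, 2 p1) + (0, delta, 0) so that the
    decomposition of g under the column's realized frequencies returns
    exactly ``alpha``; the construction leaves the dominance effect at
    ``delta`` identically.
    """
    freq = genotype_frequencies(column)
    s = additive_contrast(freq).as_array()
    base = np.array([-2.0 * freq.p2, freq.p1 - freq.p2, 2.0 * freq.p1])
    c1 = float(np.dot(s, base))
    c0 = float(s[1] * delta)
    x = (alpha - c0) / c1
    g = x * base + np.array([0.0, delta, 0.0])
    return float(g[0]), float(g[1]), float(g[2])


def _polygenic_values(
    config: SimulationConfig, spec: TraitSpec, rng: np.random.Generator
) -> np.ndarray:
    n = config.n_individuals
    if spec.sigma_a2 == 0.0:
        return np.zeros(n)
    if config.a_mode == "mvn":
        A = config.relationship_matrix
        if A is None:
            raise ValueError("a_mode='mvn' requires relationship_matrix")
        L = np.linalg.cholesky(np.asarray(A, dtype=float))
        return np.sqrt(spec.sigma_a2) * (L @ rng.standard_normal(n))
    # many small background loci at frequency 0.5, summed and rescaled
    L = config.n_background_loci
    w = rng.binomial(2, 0.5, size=(n, L)).astype(float) - 1.0
    u = rng.standard_normal(L)
    raw = w @ u
    scale = np.sqrt(spec.sigma_a2 / (0.5 * np.sum(u * u)))  # var(w_l) = 1/2
    return raw * scale


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, TruthRecord]:
    """Phenotypes y = mu + sum of causal genotypic values + a + e, per trait."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n = genotypes.n_individuals
    causal_values: dict[tuple[str, str], tuple[float, float, float]] = {}
    realized: dict[str, tuple[float, float]] = {}
    a_by_trait: dict[str, np.ndarray] = {}
    e_by_trait: dict[str, np.ndarray] = {}
    data: dict[str, dict[str, float]] = {i: {} for i in genotypes.individuals}
    for trait, spec in config.traits.items():
        a = _polygenic_values(config, spec, rng)
        e = rng.standard_normal(n) * np.sqrt(spec.sigma_e2)
        y = np.full(n, config.mu) + a + e
        for ce in config.causal:
            if ce.trait != trait:
                continue
            snp = genotypes.snps[ce.snp_index]
            col = genotypes.codes[:, ce.snp_index]
            g = causal_class_values(col, ce.alpha, ce.delta)
            causal_values[(snp.snp_id, trait)] = g
            fr = genotype_frequencies(col)
            realized[snp.snp_id] = (fr.p1, fr.p2)
            y = y + np.asarray(g)[col]
        a_by_trait[trait] = a
        e_by_trait[trait] = e
        for i, ind in enumerate(genotypes.individuals):
            data[ind][trait] = float(y[i])
    truth = TruthRecord(
        a_by_trait=a_by_trait,
        e_by_trait=e_by_trait,
        causal_values=causal_values,
        realized_freqs=realized,
        requested=list(config.causal),
    )
    return PhenotypeTable(data), truth


def simulate_pta(
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PtaTable:
    """PTAs correlated with the true polygenic value at the stated reliability.

    PTA = 0.5 * (r * a/sd_a + sqrt(1 - r^2) * z) * sd_a with r^2 the
    reliability, so corr(2*PTA, a) = r; reliability 1 gives PTA = a/2.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = config.n_individuals
    ids = [f"id{i + 1}" for i in range(n)]
    data: dict[str, dict[str, float]] = {i: {} for i in ids}
    for trait, spec in config.traits.items():
        a = truth.a_by_trait[trait]
        sd = np.sqrt(spec.sigma_a2)
        if sd == 0.0:
            pta = np.zeros(n)
        else:
            r = np.sqrt(spec.pta_reliability)
            z = rng.standard_normal(n)
            pta = 0.5 * (r * a / sd + np.sqrt(1.0 - r * r) * z) * sd
        for i, ind in enumerate(ids):
            data[ind][trait] = float(pta[i])
    return PtaTable(data)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full cohort (genotypes, phenotypes, PTAs, truth) from one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    phenotypes, truth = simulate_phenotypes(genotypes, config, rng)
    pta = simulate_pta(truth, config, rng)
    return SimulatedDataset(genotypes, phenotypes, pta, truth, config)
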