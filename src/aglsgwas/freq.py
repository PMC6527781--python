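"""Genotype/allele frequencies and additive/dominance contrast coefficients.

The additive contrast

    s_a = (P11/p1, 0.5*P12*(p2 - p1)/(p1*p2), -P22/p2)

is valid under Hardy-Weinberg disequilibrium and reduces to
(p1, p2 - p1, -p2) under Hardy-Weinberg equilibrium.  The dominance contrast
is the constant (-0.5, 1, -0.5).  Both annihilate a constant genotypic value:
s . (1, 1, 1) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING_CODE


@dataclass(frozen=True)
class SnpFrequencies:
    """Genotype and allele frequencies of one SNP over called individuals."""

    n_called: int
    P11: float
    P12: float
    P22: float

    @property
    def p1(self) -> float:
        return self.P11 + 0.5 * self.P12

    @property
    def p2(self) -> float:
        return self.P22 + 0.5 * self.P12

    @property
    def maf(self) -> float:
        return min(self.p1, self.p2)


@dataclass(frozen=True)
class ContrastCoefficients:
    kind: str  # "additive" | "dominance"
    c11: float
    c12: float
    c22: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c11, self.c12, self.c22])


def genotype_frequencies(column: np.ndarray) -> SnpFrequencies:
    """Genotype/allele frequencies of one SNP column, over called genotypes only."""
    codes = np.asarray(column)
    called = codes[codes != MISSING_CODE]
    n = called.size
    if n == 0:
        raise ValueError("no called genotypes")
    counts = np.bincount(called, minlength=3)
    return SnpFrequencies(
        n_called=int(n),
        P11=counts[0] / n,
        P12=counts[1] / n,
        P22=counts[2] / n,
    )


def additive_contrast(freq: SnpFrequencies) -> ContrastCoefficients:
    """HWD-robust additive contrast; undefined for monomorphic SNPs."""
    p1, p2 = freq.p1, freq.p2
    if p1 <= 0.0 or p2 <= 0.0:
        raise ValueError("additive contrast undefined for monomorphic SNP")
    return ContrastCoefficients(
        kind="additive",
        c11=freq.P11 / p1,
        c12=0.5 * freq.P12 * (p2 - p1) / (p1 * p2),
        c22=-freq.P22 / p2,
    )


def dominance_contrast() -> ContrastCoefficients:
    """The heterozygote-vs-homozygote-midpoint contrast (-0.5, 1, -0.5)."""
    return ContrastCoefficients(kind="dominance", c11=-0.5, c12=1.0, c22=-0.5)
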