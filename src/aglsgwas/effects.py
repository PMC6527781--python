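"""Quantitative-genetic decomposition of per-SNP genotypic values.

Given the three fitted genotypic values (g11, g12, g22) and the SNP's
genotype/allele frequencies, the decomposition yields

    mu1 = (P11/p1) g11 + 0.5 (P12/p1) g12        allelic mean of A1
    mu2 = 0.5 (P12/p2) g12 + (P22/p2) g22        allelic mean of A2
    mu  = p1 mu1 + p2 mu2                        SNP genotypic mean
    a_i = mu_i - mu                              allelic effect
    alpha = mu1 - mu2 = a1 - a2 = s_a . g        average effect of gene
                                                 substitution
    delta = g12 - (g11 + g22)/2                  dominance effect

Allelic effects about mu are not comparable across SNPs because mu differs
per SNP; comparable effects replace mu with mu_all, the unweighted mean of
mu over the reporting SNP set of the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .freq import SnpFrequencies, additive_contrast


@dataclass
class AllelicEffects:
    mu1: float
    mu2: float
    mu: float
    mu_all: float | None
    a1: float
    a2: float
    a1_comparable: float | None
    a2_comparable: float | None
    alpha: float
    delta: float | None = None
    pattern: str = ""
    dominance_mode: str = ""


def allelic_decomposition(
    g_hat: np.ndarray | tuple[float, float, float],
    freq: SnpFrequencies,
    mu_all: float | None = None,
) -> AllelicEffects:
    """Allelic means/effects and the average effect of gene substitution.

    Requires all three genotype classes; raises otherwise.  When ``mu_all``
    is given, comparable allelic effects (anchored at the across-SNP mean)
    are filled in as well.
    """
    g = np.asarray(g_hat, dtype=float)
    if g.shape != (3,) or not np.isfinite(g).all():
        raise ValueError("decomposition requires all classes")
    p1, p2 = freq.p1, freq.p2
    if p1 <= 0 or p2 <= 0:
        raise ValueError("decomposition requires a polymorphic SNP")
    g11, g12, g22 = g
    mu1 = (freq.P11 / p1) * g11 + 0.5 * (freq.P12 / p1) * g12
    mu2 = 0.5 * (freq.P12 / p2) * g12 + (freq.P22 / p2) * g22
    mu = p1 * mu1 + p2 * mu2
    a1, a2 = mu1 - mu, mu2 - mu
    eff = AllelicEffects(
        mu1=mu1, mu2=mu2, mu=mu, mu_all=mu_all,
        a1=a1, a2=a2,
        a1_comparable=(mu1 - mu_all) if mu_all is not None else None,
        a2_comparable=(mu2 - mu_all) if mu_all is not None else None,
        alpha=mu1 - mu2,
        delta=dominance_effect(g),
    )
    return eff


def dominance_effect(g_hat: np.ndarray | tuple[float, float, float]) -> float:
    """Heterozygote value minus the homozygote midpoint."""
    g = np.asarray(g_hat, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("dominance effect requires all classes")
    return float(g[1] - 0.5 * (g[0] + g[2]))


def classify_dominance_mode(
    g_hat: np.ndarray | tuple[float, float, float],
    delta: float | None = None,
    tol: float = 0.05,
) -> str:
    """Label the dominance regime of one SNP.

    Overdominance: the heterozygote lies strictly outside both homozygotes.
    Complete dominance: the heterozygote coincides with one homozygote
    (within ``tol`` times the homozygote spread).  ``none`` when delta
    vanishes on the same scale; ``partial`` otherwise.
    """
    g = np.asarray(g_hat, dtype=float)
    g11, g12, g22 = g
    if delta is None:
        delta = dominance_effect(g)
    spread = abs(g11 - g22)
    band = tol * spread
    if g12 > max(g11, g22) + band:
        return "overdominant_positive"
    if g12 < min(g11, g22) - band:
        return "overdominant_negative"
    if spread == 0.0:
        return "none" if delta == 0.0 else (
            "overdominant_positive" if delta > 0 else "overdominant_negative"
        )
    if abs(delta) <= band:
        return "none"
    if min(abs(g12 - g11), abs(g12 - g22)) <= band:
        return "complete"
    return "partial"


def classify_allelic_pattern(
    a1_comparable: float,
    a2_comparable: float,
    thresholds: tuple[float, float] = (0.2, 0.8),
) -> str:
    """Classify the two comparable allelic effects of a SNP.

    With r = min(|a1|, |a2|) / max(|a1|, |a2|): uni-allelic (one active, one
    neutral allele) when r <= thresholds[0]; symmetric (similar magnitudes,
    opposite directions) when r >= thresholds[1] and the signs oppose;
    asymmetric otherwise.  The sign suffix follows the active / larger
    allele's direction.
    """
    lo, hi = thresholds
    m1, m2 = abs(a1_comparable), abs(a2_comparable)
    if m1 == 0.0 and m2 == 0.0:
        return "none"
    big = a1_comparable if m1 >= m2 else a2_comparable
    suffix = "positive" if big > 0 else "negative"
    r = min(m1, m2) / max(m1, m2)
    if r <= lo:
        return f"uniallelic_{suffix}"
    if r >= hi and a1_comparable * a2_comparable < 0:
        return "symmetric"
    return f"asymmetric_{suffix}"


def compute_mu_all(mus: Iterable[float]) -> float:
    """Unweighted mean of SNP genotypic means over the reporting SNP set."""
    arr = np.asarray(list(mus), dtype=float)
    if arr.size == 0:
        raise ValueError("empty reporting set")
    return float(arr.mean())


def alpha_from_contrast(g_hat, freq: SnpFrequencies) -> float:
    """alpha via the additive contrast, s_a . g_hat (identity with mu1 - mu2)."""
    s = additive_contrast(freq).as_array()
    return float(np.dot(s, np.asarray(g_hat, dtype=float)))
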