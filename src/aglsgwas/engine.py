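"""Per-SNP AGLS estimation and t-tests of additive and dominance contrasts.

The AGLS (approximate generalized least squares) device: phenotypic yield
deviations are pre-adjusted by twice the predicted transmitting ability,
y* = y - 2*PTA, which removes an external estimate of the additive polygenic
value in place of the BLUP that exact mixed-model equations would supply.
The per-SNP model is then an ordinary cell-means fit of y* on the three
genotype classes, and additive/dominance hypotheses are tested as contrasts
of the fitted class means:

    t_j = |s_j' g_hat| / sqrt(v2 * s_j' (X'X)_gg^- s_j),   j in {a, d}

with v2 = RSS / (n - k), k = number of genotype classes present.  Under the
cell-means parameterization (X'X)_gg^- is diagonal with entries 1/n_class.

Two-sided p-values come from the t distribution with n - k degrees of
freedom.  When the exact tail underflows below the smallest representable
double (p < 1e-308), log10(1/p) is extrapolated by an empirical power law
in t (default coefficients 0.2416, 1.9713) and the row is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    MISSING_CODE,
    GenotypeMatrix,
    PhenotypeTable,
    PtaTable,
    ResultRow,
)
from .effects import (
    allelic_decomposition,
    classify_dominance_mode,
    compute_mu_all,
    dominance_effect,
)
from .freq import SnpFrequencies, additive_contrast, dominance_contrast, genotype_frequencies

log = logging.getLogger("aglsgwas")

#: p-values below this are treated as underflowed and extrapolated.
UNDERFLOW_P = 1e-308


@dataclass
class AglsConfig:
    """Tuning knobs of the AGLS scan."""

    min_class_count: int = 5            # dominance needs all 3 classes this big
    empirical_coeffs: tuple[float, float] = (0.2416, 1.9713)
    maf_reporting_min: float = 0.05     # gates effect reporting, not testing
    pattern_thresholds: tuple[float, float] = (0.2, 0.8)
    complete_dominance_tol: float = 0.05


@dataclass
class SnpFit:
    """Cell-means fit of adjusted phenotypes on one SNP's genotype classes."""

    g_hat: np.ndarray          # (g11, g12, g22); NaN where class absent
    class_counts: np.ndarray   # observations per class
    v2: float                  # residual variance, RSS/(n-k)
    n: int
    k: int                     # classes present = rank of the design
    dominance_untestable: bool

    @property
    def xtx_gg_inv(self) -> np.ndarray:
        """Diagonal of the generalized inverse crossproduct block (1/n_class)."""
        with np.errstate(divide="ignore"):
            return np.where(self.class_counts > 0, 1.0 / self.class_counts, np.nan)


@dataclass
class TestResult:
    t_add: float
    log10invp_add: float
    t_dom: float | None
    log10invp_dom: float | None
    empirical_p_used: bool
    dominance_untestable: bool


def adjust_phenotypes(
    phenotypes: PhenotypeTable, pta: PtaTable, trait: str
) -> tuple[list[str], np.ndarray]:
    """PTA-adjust one trait: y* = y - 2*PTA over individuals having both.

    Returns the retained individual ids and the adjusted vector; individuals
    missing either value are dropped (the count is logged).
    """
    y = phenotypes.trait_series(trait)
    a = pta.trait_series(trait) if trait in pta.traits else None
    if a is None:
        raise ValueError(f"trait {trait!r} absent from PTA table")
    common = y.index.intersection(a.index)
    n_drop = len(y.index.union(a.index)) - len(common)
    if len(common) == 0:
        raise ValueError(f"no individuals with both phenotype and PTA for {trait!r}")
    if n_drop:
        log.info("trait %s: dropped %d individuals lacking phenotype or PTA", trait, n_drop)
    y_star = y.loc[common].to_numpy() - 2.0 * a.loc[common].to_numpy()
    return list(common), y_star


def fit_snp(y_star: np.ndarray, codes: np.ndarray, min_class_count: int = 5) -> SnpFit:
    """Cell-means least squares of adjusted phenotypes on one SNP.

    Missing genotypes and missing phenotypes are dropped pairwise.  Requires
    at least two genotype classes among the retained individuals.
    """
    y = np.asarray(y_star, dtype=float)
    c = np.asarray(codes)
    keep = (c != MISSING_CODE) & np.isfinite(y)
    y, c = y[keep], c[keep]
    counts = np.bincount(c, minlength=3).astype(float)
    k = int((counts > 0).sum())
    if k < 2:
        raise ValueError("SNP monomorphic in sample")
    n = int(counts.sum())
    if n <= k:
        raise ValueError("too few observations for residual variance")
    sums = np.bincount(c, weights=y, minlength=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_hat = np.where(counts > 0, sums / counts, np.nan)
    sumsq = np.bincount(c, weights=y * y, minlength=3)
    safe_counts = np.where(counts > 0, counts, 1.0)
    rss = float(np.nansum(sumsq - np.where(counts > 0, sums**2 / safe_counts, 0.0)))
    rss = max(rss, 0.0)  # guard tiny negative round-off
    untestable = bool((counts < min_class_count).any())
    return SnpFit(
        g_hat=g_hat,
        class_counts=counts,
        v2=rss / (n - k),
        n=n,
        k=k,
        dominance_untestable=untestable,
    )


def empirical_log10p(t: float, coeffs: tuple[float, float] = (0.2416, 1.9713)) -> float:
    """Power-law extrapolation of log10(1/p) for t-values whose exact tail underflows."""
    if t < 0:
        raise ValueError("t must be non-negative")
    coef, expo = coeffs
    return coef * t**expo


def fit_empirical_tail(
    t_values: np.ndarray, log10invp: np.ndarray
) -> tuple[float, float]:
    """Refit the (coefficient, exponent) of the extrapolation law.

    Least squares of log10(log10(1/p)) on log10(t) over pairs where both are
    positive and representable; returns (coefficient, exponent).
    """
    t = np.asarray(t_values, float)
    lp = np.asarray(log10invp, float)
    ok = (t > 0) & (lp > 0) & np.isfinite(t) & np.isfinite(lp)
    if ok.sum() < 2:
        raise ValueError("need at least two representable (t, log10invp) pairs")
    slope, intercept = np.polyfit(np.log10(t[ok]), np.log10(lp[ok]), 1)
    return 10.0**intercept, slope


def _contrast_t(
    s: np.ndarray, fit: SnpFit, active: np.ndarray
) -> tuple[float, float, bool]:
    """t and log10(1/p) for one contrast restricted to active classes."""
    g = fit.g_hat[active]
    var_scale = float(np.sum(s[active] ** 2 / fit.class_counts[active]))
    num = abs(float(np.dot(s[active], g)))
    denom = math.sqrt(fit.v2 * var_scale) if fit.v2 > 0 else 0.0
    if denom == 0.0:
        t = 0.0 if num == 0.0 else math.inf
    else:
        t = num / denom
    df = fit.n - fit.k
    if math.isinf(t):
        return t, math.inf, True
    p = 2.0 * stats.t.sf(t, df)
    if p >= UNDERFLOW_P:
        return t, -math.log10(p), False
    return t, empirical_log10p(t), True


def snp_tests(fit: SnpFit, freq: SnpFrequencies, config: AglsConfig | None = None) -> TestResult:
    """Additive and dominance contrast t-tests for one fitted SNP."""
    config = config or AglsConfig()
    s_a = additive_contrast(freq).as_array()
    present = fit.class_counts > 0
    t_add, lp_add, emp_a = _contrast_t(s_a, fit, present)
    if fit.dominance_untestable:
        t_dom = lp_dom = None
        emp_d = False
    else:
        s_d = dominance_contrast().as_array()
        t_dom, lp_dom, emp_d = _contrast_t(s_d, fit, present)
    return TestResult(
        t_add=t_add,
        log10invp_add=lp_add,
        t_dom=t_dom,
        log10invp_dom=lp_dom,
        empirical_p_used=emp_a or emp_d,
        dominance_untestable=fit.dominance_untestable,
    )


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    pta: PtaTable,
    traits: list[str] | None = None,
    config: AglsConfig | None = None,
) -> list[ResultRow]:
    """Full single-marker scan: one ResultRow per (SNP, trait).

    Per trait: PTA-adjust phenotypes, fit every SNP by cell means, test the
    additive and dominance contrasts, decompose allelic effects, anchor
    comparable allelic effects at the across-SNP mean genotypic value of the
    reporting (MAF-filtered) SNP set, and assign dense significance ranks.
    """
    from .report import ReportConfig, rank_and_filter  # local import: avoid cycle

    config = config or AglsConfig()
    traits = traits or phenotypes.traits
    geno_index = {ind: i for i, ind in enumerate(genotypes.individuals)}
    all_rows: list[ResultRow] = []
    for trait in traits:
        ids, y_star_vec = adjust_phenotypes(phenotypes, pta, trait)
        rows_idx = [geno_index[i] for i in ids if i in geno_index]
        kept = [i for i in ids if i in geno_index]
        if not kept:
            raise ValueError(f"no overlapping individuals between genotypes and trait {trait!r}")
        if len(kept) < len(ids):
            log.info("trait %s: %d phenotyped individuals lack genotypes", trait, len(ids) - len(kept))
        y_by_id = dict(zip(ids, y_star_vec))
        y = np.array([y_by_id[i] for i in kept])
        sub_codes = genotypes.codes[rows_idx, :]
        trait_rows: list[ResultRow] = []
        for j, snp in enumerate(genotypes.snps):
            col = sub_codes[:, j]
            keep = col != MISSING_CODE
            freq = genotype_frequencies(col[keep]) if keep.any() else None
            row = ResultRow(
                snp_id=snp.snp_id, chrom=snp.chrom, pos_bp=snp.pos_bp,
                allele1=snp.allele1, allele2=snp.allele2, trait=trait,
                n_used=0, p1=np.nan, p2=np.nan, P11=np.nan, P12=np.nan,
                P22=np.nan, maf=np.nan,
            )
            if freq is None:
                trait_rows.append(row)
                continue
            row.p1, row.p2 = freq.p1, freq.p2
            row.P11, row.P12, row.P22 = freq.P11, freq.P12, freq.P22
            row.maf = freq.maf
            try:
                fit = fit_snp(y, col, config.min_class_count)
            except ValueError:
                row.n_used = int(freq.n_called)
                row.dominance_untestable = True
                trait_rows.append(row)
                continue
            row.n_used = fit.n
            g11, g12, g22 = fit.g_hat
            row.g11_hat, row.g12_hat, row.g22_hat = g11, g12, g22
            tr = snp_tests(fit, freq, config)
            row.t_add, row.log10invp_add = tr.t_add, tr.log10invp_add
            row.dominance_untestable = tr.dominance_untestable
            row.empirical_p_used = tr.empirical_p_used
            if tr.t_dom is not None:
                row.t_dom, row.log10invp_dom = tr.t_dom, tr.log10invp_dom
            if fit.k == 3:
                eff = allelic_decomposition(fit.g_hat, freq, mu_all=None)
                row.alpha, row.a1, row.a2 = eff.alpha, eff.a1, eff.a2
                row.delta = dominance_effect(fit.g_hat)
                row.dominance_mode = classify_dominance_mode(
                    fit.g_hat, row.delta, tol=config.complete_dominance_tol
                )
            else:
                # absent class has zero frequency hence zero contrast weight
                s_a = additive_contrast(freq).as_array()
                present = fit.class_counts > 0
                row.alpha = float(np.dot(s_a[present], fit.g_hat[present]))
            trait_rows.append(row)
        _attach_comparable_effects(trait_rows, config)
        all_rows.extend(trait_rows)
    report_cfg = ReportConfig(maf_reporting_min=config.maf_reporting_min)
    return rank_and_filter(all_rows, report_cfg)


def _attach_comparable_effects(trait_rows: list[ResultRow], config: AglsConfig) -> None:
    """Anchor allelic effects at mu_all of the reporting SNP set and classify patterns."""
    from .effects import classify_allelic_pattern

    mus = [
        _mu_of(r)
        for r in trait_rows
        if np.isfinite(r.a1) and r.maf >= config.maf_reporting_min
    ]
    if not mus:
        return
    mu_all = compute_mu_all(mus)
    for r in trait_rows:
        if not np.isfinite(r.a1):
            continue
        mu = _mu_of(r)
        r.a1_comparable = r.a1 + mu - mu_all
        r.a2_comparable = r.a2 + mu - mu_all
        r.pattern = classify_allelic_pattern(
            r.a1_comparable, r.a2_comparable, thresholds=config.pattern_thresholds
        )


def _mu_of(r: ResultRow) -> float:
    """SNP genotypic mean mu = p1*mu1 + p2*mu2 from the stored class means."""
    P11, P12, P22 = r.P11, r.P12, r.P22
    p1, p2 = r.p1, r.p2
    m1 = (P11 / p1) * r.g11_hat + 0.5 * (P12 / p1) * r.g12_hat
    m2 = 0.5 * (P12 / p2) * r.g12_hat + (P22 / p2) * r.g22_hat
    return p1 * m1 + p2 * m2
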