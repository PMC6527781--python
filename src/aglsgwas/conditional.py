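"""Conditional re-analysis around an index SNP.

To measure how much of a regional signal cluster is linkage disequilibrium
with one index SNP, the index SNP's fitted genotypic values are subtracted
from the adjusted phenotypes (each individual loses the class mean of its
index genotype) and the region is re-scanned with the same per-SNP
machinery.  Top-fraction effects that survive conditioning are counted
against the unconditional per-trait significance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING_CODE, GenotypeMatrix, ResultRow, SnpRecord
from .engine import AglsConfig, fit_snp, snp_tests, SnpFit
from .freq import genotype_frequencies


@dataclass
class ConditionalReport:
    index_snp: SnpRecord
    traits: list[str]
    n_region_snps: int
    top_fraction: float
    #: per trait: (top-fraction count before, count surviving after)
    counts: dict[str, tuple[int, int]]
    #: per trait: list of (snp_id, log10invp before, log10invp after)
    pairs: dict[str, list[tuple[str, float, float]]]


def residualize_on_index(
    y_star: np.ndarray, index_codes: np.ndarray, index_fit: SnpFit
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the index SNP's class means from adjusted phenotypes.

    Returns (residual vector, keep mask); individuals with a missing index
    genotype are excluded by the mask.
    """
    if index_fit.k < 2:
        raise ValueError("index SNP monomorphic")
    y = np.asarray(y_star, dtype=float)
    c = np.asarray(index_codes)
    keep = (c != MISSING_CODE) & np.isfinite(y)
    resid = np.full(y.shape, np.nan)
    resid[keep] = y[keep] - index_fit.g_hat[c[keep]]
    return resid, keep


def _scan_columns(
    y: np.ndarray,
    codes: np.ndarray,
    snps: list[SnpRecord],
    trait: str,
    config: AglsConfig,
) -> list[ResultRow]:
    rows = []
    for j, snp in enumerate(snps):
        col = codes[:, j]
        called = col != MISSING_CODE
        row = ResultRow(
            snp_id=snp.snp_id, chrom=snp.chrom, pos_bp=snp.pos_bp,
            allele1=snp.allele1, allele2=snp.allele2, trait=trait,
            n_used=0, p1=np.nan, p2=np.nan, P11=np.nan, P12=np.nan,
            P22=np.nan, maf=np.nan,
        )
        if not called.any():
            rows.append(row)
            continue
        freq = genotype_frequencies(col[called & np.isfinite(y)])
        row.p1, row.p2 = freq.p1, freq.p2
        row.P11, row.P12, row.P22 = freq.P11, freq.P12, freq.P22
        row.maf = freq.maf
        try:
            fit = fit_snp(y, col, config.min_class_count)
        except ValueError:
            row.dominance_untestable = True
            rows.append(row)
            continue
        row.n_used = fit.n
        row.g11_hat, row.g12_hat, row.g22_hat = fit.g_hat
        tr = snp_tests(fit, freq, config)
        row.t_add, row.log10invp_add = tr.t_add, tr.log10invp_add
        row.dominance_untestable = tr.dominance_untestable
        row.empirical_p_used = tr.empirical_p_used
        if tr.t_dom is not None:
            row.t_dom, row.log10invp_dom = tr.t_dom, tr.log10invp_dom
        rows.append(row)
    return rows


def conditional_scan(
    genotypes: GenotypeMatrix,
    region: tuple[str, int, int],
    y_resid_by_trait: dict[str, np.ndarray],
    traits: list[str] | None = None,
    config: AglsConfig | None = None,
) -> list[ResultRow]:
    """Re-scan the SNPs of ``region`` on residualized phenotypes.

    ``y_resid_by_trait`` maps trait name to a residual vector aligned with
    ``genotypes.individuals`` (NaN where the individual is dropped).
    """
    config = config or AglsConfig()
    chrom, start, end = region
    idx = [
        j for j, s in enumerate(genotypes.snps)
        if s.chrom == str(chrom) and start <= s.pos_bp <= end
    ]
    if not idx:
        raise ValueError(f"empty region {chrom}:{start}-{end}")
    sub = genotypes.subset_snps(idx)
    traits = traits or list(y_resid_by_trait)
    rows: list[ResultRow] = []
    for trait in traits:
        rows.extend(_scan_columns(y_resid_by_trait[trait], sub.codes, sub.snps, trait, config))
    return rows


def retention_summary(
    before: list[ResultRow],
    after: list[ResultRow],
    index_snp: SnpRecord,
    fraction: float = 0.01,
) -> ConditionalReport:
    """Count top-fraction effects before conditioning and survivors after.

    A (SNP, trait) effect is "top fraction" when its unconditional rank is
    within ceiling(fraction * tested SNPs) for the trait; survival after
    conditioning is judged against the unconditional trait-specific
    log10(1/p) cutoff (the weakest top-fraction value).
    """
    def grid(rows):
        return {(r.snp_id, r.trait) for r in rows}

    if grid(before) != grid(after):
        raise ValueError("before/after rows cover different SNP x trait grids")
    traits = sorted({r.trait for r in before})
    counts: dict[str, tuple[int, int]] = {}
    pairs: dict[str, list[tuple[str, float, float]]] = {}
    after_by_key = {(r.snp_id, r.trait): r for r in after}
    for trait in traits:
        b = [r for r in before if r.trait == trait and np.isfinite(r.log10invp_add)]
        n_tested = len(b)
        n_top = math.ceil(fraction * n_tested)
        b_sorted = sorted(b, key=lambda r: -r.log10invp_add)
        top = b_sorted[:n_top]
        cutoff = top[-1].log10invp_add if top else math.inf
        survived = 0
        plist = []
        for r in top:
            a = after_by_key[(r.snp_id, trait)]
            lp_after = a.log10invp_add if np.isfinite(a.log10invp_add) else 0.0
            if lp_after >= cutoff:
                survived += 1
            plist.append((r.snp_id, r.log10invp_add, lp_after))
        counts[trait] = (len(top), survived)
        pairs[trait] = plist
    return ConditionalReport(
        index_snp=index_snp,
        traits=traits,
        n_region_snps=len({r.snp_id for r in before}),
        top_fraction=fraction,
        counts=counts,
        pairs=pairs,
    )
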