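"""Thresholding, ranking, reporting filters and plot-data emission."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ResultRow, rows_to_frame


@dataclass
class ReportConfig:
    alpha_genomewide: float = 0.05
    maf_reporting_min: float = 0.05
    top_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_genomewide < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.maf_reporting_min <= 0.5:
            raise ValueError("maf_reporting_min must be in [0, 0.5]")


def bonferroni_threshold(
    alpha: float, n_snps: int, n_traits: int = 1
) -> tuple[float, float]:
    """Genome-wide p threshold alpha/(n_snps * n_traits).

    Returns (exact, rounded-to-one-significant-order-of-magnitude); the
    rounded form is the operational threshold (e.g. 1e-7 for 0.05 over
    57,067 SNPs x 9 traits).
    """
    if n_snps <= 0 or n_traits <= 0 or alpha <= 0:
        raise ValueError("alpha, n_snps and n_traits must be positive")
    exact = alpha / (n_snps * n_traits)
    rounded = 10.0 ** round(math.log10(exact))
    return exact, rounded


def _dense_ranks(rows: list[ResultRow], key: str) -> dict[int, int]:
    """1-based dense ranks by descending log10(1/p); ties by |alpha| then snp_id."""
    scored = [
        (i, getattr(rows[i], key), abs(rows[i].alpha) if np.isfinite(rows[i].alpha) else -1.0)
        for i in range(len(rows))
        if getattr(rows[i], key) is not None and np.isfinite(getattr(rows[i], key))
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], rows[t[0]].snp_id))
    ranks: dict[int, int] = {}
    rank = 0
    prev = None
    for i, lp, _ in scored:
        if prev is None or lp != prev:
            rank += 1
            prev = lp
        ranks[i] = rank
    return ranks


def rank_and_filter(rows: list[ResultRow], config: ReportConfig | None = None) -> list[ResultRow]:
    """Assign per-trait dense significance ranks and reporting flags in place.

    Never changes any statistic — only ranks and visibility flags.  Effect
    sizes of SNPs below the reporting MAF stay in the table but carry the
    ``effect_suppressed_low_maf`` flag.
    """
    config = config or ReportConfig()
    for trait in sorted({r.trait for r in rows}):
        trait_rows = [r for r in rows if r.trait == trait]
        add_ranks = _dense_ranks(trait_rows, "log10invp_add")
        dom_ranks = _dense_ranks(trait_rows, "log10invp_dom")
        for i, r in enumerate(trait_rows):
            r.rank_add = add_ranks.get(i)
            r.rank_dom = dom_ranks.get(i)
            if np.isfinite(r.maf) and r.maf < config.maf_reporting_min:
                r.effect_suppressed_low_maf = True
    return rows


def manhattan_table(rows: list[ResultRow], p_threshold: float = 1e-7) -> pd.DataFrame:
    """Per-trait plot data: chrom, pos, log10(1/p), significance flag.

    Sorted by chromosome then position; the flag compares the additive
    log10(1/p) against -log10 of the operational threshold.
    """
    df = rows_to_frame(rows)
    cut = -math.log10(p_threshold)
    out = df[["trait", "chrom", "pos_bp", "snp_id", "log10invp_add", "log10invp_dom"]].copy()
    out["significant_add"] = out["log10invp_add"] >= cut
    out["significant_dom"] = out["log10invp_dom"] >= cut
    key = out["chrom"].astype(str)
    num = pd.to_numeric(key, errors="coerce")
    out = (
        out.assign(_cnum=num.fillna(np.inf), _c=key)
        .sort_values(["trait", "_cnum", "_c", "pos_bp"], kind="mergesort")
        .drop(columns=["_cnum", "_c"])
        .reset_index(drop=True)
    )
    return out
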