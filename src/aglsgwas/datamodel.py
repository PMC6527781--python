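"""Core domain types: SNP records, genotype matrices, trait tables, result rows.

Genotype coding convention: each cell holds the count of allele2 carried by
the individual (0 = A1A1, 1 = A1A2, 2 = A2A2); missing genotypes are stored
as ``MISSING_CODE`` (-1).  Allele1 is the first-listed allele of the SNP map
(REF for VCF, the non-counted allele for PLINK .raw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING_CODE = -1


@dataclass(frozen=True)
class SnpRecord:
    """Identity of one biallelic SNP."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.snp_id}")
        if self.allele1 == self.allele2:
            raise ValueError(f"alleles must differ for {self.snp_id}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of allele2 counts.

    ``codes`` is an int8 array of shape (n_individuals, n_snps) with entries
    in {0, 1, 2, MISSING_CODE}.
    """

    individuals: list[str]
    snps: list[SnpRecord]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.individuals):
            raise ValueError("row count != individual count")
        if m != len(self.snps):
            raise ValueError("column count != SNP count")
        valid = np.isin(self.codes, (0, 1, 2, MISSING_CODE))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in dataset")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(f"SNP {snp_id!r} not in matrix")

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.snp_index(snp_id)]

    def subset_snps(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=[self.snps[j] for j in idx],
            codes=self.codes[:, idx].copy(),
        )


class _TraitTable:
    """Individual x trait table backed by a float DataFrame; NaN = absent."""

    def __init__(self, data: pd.DataFrame | Mapping[str, Mapping[str, float]]):
        if isinstance(data, pd.DataFrame):
            df = data.astype(float)
        else:
            df = pd.DataFrame({i: dict(tr) for i, tr in data.items()}).T.astype(float)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate individual id {dup!r}")
        if np.isinf(df.to_numpy()).any():
            raise ValueError("non-finite trait values")
        df.index = df.index.astype(str)
        self._df = df

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def individuals(self) -> list[str]:
        return list(self._df.index)

    @property
    def traits(self) -> list[str]:
        return list(self._df.columns)

    def value(self, individual: str, trait: str) -> float:
        return float(self._df.at[individual, trait])

    def has(self, individual: str, trait: str) -> bool:
        return (
            individual in self._df.index
            and trait in self._df.columns
            and not pd.isna(self._df.at[individual, trait])
        )

    def trait_series(self, trait: str) -> pd.Series:
        return self._df[trait].dropna()

    def __eq__(self, other) -> bool:  # mainly for round-trip tests
        return isinstance(other, _TraitTable) and self._df.equals(other._df)


class PhenotypeTable(_TraitTable):
    """Yield deviations (trait units) per individual and trait."""


class PtaTable(_TraitTable):
    """Predicted transmitting abilities (half breeding-value units)."""


# Column order of the results table; status flags last.
RESULT_COLUMNS = [
    "snp_id", "chrom", "pos_bp", "allele1", "allele2", "trait", "n_used",
    "p1", "p2", "P11", "P12", "P22", "maf",
    "g11_hat", "g12_hat", "g22_hat",
    "alpha", "a1", "a2", "a1_comparable", "a2_comparable", "delta",
    "t_add", "log10invp_add", "t_dom", "log10invp_dom",
    "rank_add", "rank_dom",
    "dominance_untestable", "effect_suppressed_low_maf", "empirical_p_used",
]


@dataclass
class ResultRow:
    """One (SNP, trait) line of the association scan output."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str
    trait: str
    n_used: int
    p1: float
    p2: float
    P11: float
    P12: float
    P22: float
    maf: float
    g11_hat: float = np.nan
    g12_hat: float = np.nan
    g22_hat: float = np.nan
    alpha: float = np.nan
    a1: float = np.nan
    a2: float = np.nan
    a1_comparable: float = np.nan
    a2_comparable: float = np.nan
    delta: float = np.nan
    t_add: float = np.nan
    log10invp_add: float = np.nan
    t_dom: float = np.nan
    log10invp_dom: float = np.nan
    rank_add: int | None = None
    rank_dom: int | None = None
    dominance_untestable: bool = False
    effect_suppressed_low_maf: bool = False
    empirical_p_used: bool = False
    pattern: str = field(default="", compare=False)
    dominance_mode: str = field(default="", compare=False)


def rows_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    """Tabulate ResultRows in the stable output column order."""
    if not rows:
        raise ValueError("no result rows")
    recs = []
    for r in rows:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        recs.append(d)
    df = pd.DataFrame.from_records(recs)
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    return df[RESULT_COLUMNS + extra]
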