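"""Readers and writers for genotype matrices, trait tables and result tables.

Three genotype dialects are supported:

* ``tsv`` — header ``id<TAB>snp1<TAB>...``, codes 0/1/2, missing ``NA``, with a
  companion SNP map file ``snp_id<TAB>chrom<TAB>pos<TAB>allele1<TAB>allele2``;
* ``plink_raw`` — PLINK ``--recode A`` additive dosages; the counted allele in
  each ``SNP_A`` header token is allele2;
* ``vcf`` — GT fields of biallelic records via cyvcf2; ALT is allele2.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING_CODE,
    RESULT_COLUMNS,
    GenotypeMatrix,
    PhenotypeTable,
    PtaTable,
    ResultRow,
    SnpRecord,
    rows_to_frame,
)

log = logging.getLogger("aglsgwas")

_CODE_SET = {"0", "1", "2"}


def read_snp_map(path: str | Path) -> list[SnpRecord]:
    """Read the companion SNP map (snp_id, chrom, pos, allele1, allele2)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: malformed map line {lineno}: expected 5 fields")
            snp_id, chrom, pos, a1, a2 = parts
            try:
                pos_bp = int(pos)
            except ValueError:
                raise ValueError(f"{path}: non-integer position at line {lineno}") from None
            records.append(SnpRecord(snp_id, chrom, pos_bp, a1, a2))
    return records


def write_snp_map(snps: list[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos_bp}\t{s.allele1}\t{s.allele2}\n")


def _read_tsv_genotypes(path: str | Path, map_path: str | Path | None) -> GenotypeMatrix:
    individuals: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: line 1: expected header starting with 'id'")
        snp_ids = header[1:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            individuals.append(parts[0])
            row = []
            for tok in parts[1:]:
                if tok == "NA":
                    row.append(MISSING_CODE)
                elif tok in _CODE_SET:
                    row.append(int(tok))
                else:
                    raise ValueError(f"{path}: line {lineno}: invalid genotype code {tok!r}")
            rows.append(row)
    if map_path is not None:
        snps = read_snp_map(map_path)
        by_id = {s.snp_id: s for s in snps}
        missing = [sid for sid in snp_ids if sid not in by_id]
        if missing:
            raise ValueError(f"SNPs missing from map: {missing[:5]}")
        snps = [by_id[sid] for sid in snp_ids]
    else:
        snps = [SnpRecord(sid, "0", j + 1, "A", "B") for j, sid in enumerate(snp_ids)]
    codes = np.asarray(rows, dtype=np.int8).reshape(len(individuals), len(snp_ids))
    return GenotypeMatrix(individuals, snps, codes)


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path: str | Path, map_path: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    for col in _PLINK_META:
        if col not in df.columns:
            raise ValueError(f"{path}: missing PLINK .raw column {col!r}")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    snps = []
    for j, col in enumerate(snp_cols):
        # header token is "<snp_id>_<counted allele>"; counted allele = allele2
        snp_id, _, counted = col.rpartition("_")
        if not snp_id:
            raise ValueError(f"{path}: SNP column {col!r} lacks a counted-allele suffix")
        other = "?" if counted == "?" else ("B" if counted != "B" else "A")
        snps.append(SnpRecord(snp_id, "0", j + 1, other, counted))
    codes = df[snp_cols].to_numpy(dtype=float)
    out = np.full(codes.shape, MISSING_CODE, dtype=np.int8)
    called = ~np.isnan(codes)
    out[called] = codes[called].astype(np.int8)
    gm = GenotypeMatrix(list(df["IID"].astype(str)), snps, out)
    if map_path is not None:
        by_id = {s.snp_id: s for s in read_snp_map(map_path)}
        gm.snps = [by_id.get(s.snp_id, s) for s in gm.snps]
    return gm


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING_CODE, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping non-biallelic record {var.ID or var.POS}")
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        cols.append(remap[var.gt_types])
    codes = np.column_stack(cols) if cols else np.zeros((len(individuals), 0), np.int8)
    return GenotypeMatrix(individuals, snps, codes)


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    map_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    Codes are always oriented as counts of allele2 (ALT for VCF, the counted
    allele for PLINK .raw, the map's second allele for TSV).
    """
    if dialect == "tsv":
        return _read_tsv_genotypes(path, map_path)
    if dialect == "plink_raw":
        return _read_plink_raw(path, map_path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the TSV genotype dialect (and optionally its companion map)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(s.snp_id for s in gm.snps) + "\n")
        for i, ind in enumerate(gm.individuals):
            toks = ["NA" if c == MISSING_CODE else str(int(c)) for c in gm.codes[i]]
            fh.write(ind + "\t" + "\t".join(toks) + "\n")
    if map_path is not None:
        write_snp_map(gm.snps, map_path)


def read_trait_table(path: str | Path, kind: str = "phenotype") -> PhenotypeTable | PtaTable:
    """Read a trait table: header ``id<TAB>trait...``, one row per individual.

    Empty cells become absent entries.  Duplicated ids and non-numeric cells
    are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: first column must be 'id'")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    df = df.set_index("id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            cell = f"({bad.index[0]}, {col})"
            raise ValueError(f"{path}: non-numeric cell at {cell}") from None
    cls = PhenotypeTable if kind == "phenotype" else PtaTable
    return cls(df)


def write_trait_table(table: PhenotypeTable | PtaTable, path: str | Path) -> None:
    df = table.frame
    # %.17g keeps doubles bit-exact through the round trip
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g", na_rep="")


def write_results(rows: list[ResultRow], path: str | Path) -> None:
    """Write the results table (tab-separated, stable column order)."""
    df = rows_to_frame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"snp_id": str, "chrom": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return df
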