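"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel as VCF 4.2 (GT field) or as a samples x SNPs dosage TSV;
phenotypes, per-SNP association results and gene scores as TSV; gene models
as BED (0-based, half-open); gene sets as GMT.  Every writer emits bytes that
are a pure function of its inputs so that fixture files are reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError

MISSING_DOSAGE = -1

PHENOTYPE_COLUMNS = ["sample_id", "status", "age", "pc1", "pc2", "pc3", "stratum"]
DEFAULT_COVARIATES = ("age", "pc1", "pc2", "pc3")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages for a cohort, with per-sample stratum labels.

    ``dosages`` is an ``(n_samples, n_snps)`` int8 array of alternate-allele
    counts in {0, 1, 2}, with :data:`MISSING_DOSAGE` marking missing calls.
    SNP positions are 1-based.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    stratum: np.ndarray
    maf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.stratum = np.asarray(self.stratum, dtype=object)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ParseError("duplicate SNP ids in genotype matrix")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ParseError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        valid = np.isin(self.dosages, [MISSING_DOSAGE, 0, 1, 2])
        if not valid.all():
            raise ParseError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        rows = np.array([index[s] for s in sample_ids], dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[rows],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            dosages=self.dosages[rows],
            stratum=self.stratum[rows],
            maf=self.maf,
        )


# ---------------------------------------------------------------------------
# VCF

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 with a GT FORMAT field.

    Alleles are placeholders (REF=A, ALT=G); the stratum of each sample is
    recorded in a ``##SAMPLE`` header line so a VCF round-trip preserves it.
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(genotypes.chrom):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid, stratum in zip(genotypes.sample_ids, genotypes.stratum):
        lines.append(f"##SAMPLE=<ID={sid},Stratum={stratum}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, genotypes.sample_ids))
    )
    dosages = genotypes.dosages
    for j in range(genotypes.n_snps):
        gts = "\t".join(_VCF_GT[int(d)] for d in dosages[:, j])
        lines.append(
            f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}"
            f"\tA\tG\t.\t.\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Genotype calls are collapsed to alternate-allele dosage; any missing
    allele makes the whole call missing.  Stratum labels are recovered from
    ``##SAMPLE`` header lines when present, otherwise every sample is placed
    in a single stratum.
    """
    strata: dict[str, str] = {}
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in str(vcf.header).splitlines():
            if rec.startswith("##SAMPLE=<") and "Stratum=" in rec:
                body = rec[len("##SAMPLE=<"):].rstrip(">")
                fields = dict(kv.split("=", 1) for kv in body.split(","))
                strata[fields["ID"]] = fields["Stratum"]
        samples = list(vcf.header.samples)
        snp_ids, chroms, poss, rows = [], [], [], []
        for rec in vcf:
            snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            poss.append(rec.pos)  # pysam exposes 1-based POS
            row = np.empty(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                alleles = rec.samples[sample]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    row[i] = MISSING_DOSAGE
                else:
                    row[i] = sum(1 for a in alleles if a != 0)
            rows.append(row)
    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    stratum = np.array([strata.get(s, "stratum_1") for s in samples], dtype=object)
    return GenotypeMatrix(
        sample_ids=np.array(samples, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosages=dosages,
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# Dosage TSV

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Samples x SNPs dosage matrix; header row of SNP ids, -1 for missing."""
    with open(path, "w") as fh:
        fh.write("sample_id\tstratum\t" + "\t".join(map(str, genotypes.snp_ids)) + "\n")
        for i, sid in enumerate(genotypes.sample_ids):
            row = "\t".join(str(int(d)) for d in genotypes.dosages[i])
            fh.write(f"{sid}\t{genotypes.stratum[i]}\t{row}\n")


def read_dosage_tsv(path, snp_table: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a dosage TSV.

    The TSV does not carry SNP coordinates; pass ``snp_table`` (columns
    snp_id, chrom, pos) to restore them, e.g. from the companion VCF.
    Without it chrom/pos are filled with placeholders and the matrix cannot
    be used for gene mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stratum": str})
    if df.columns[0] != "sample_id" or df.columns[1] != "stratum":
        raise ParseError("dosage TSV must start with sample_id and stratum columns")
    snp_ids = np.array(df.columns[2:], dtype=object)
    dosages = df.iloc[:, 2:].to_numpy(dtype=np.int8)
    if snp_table is not None:
        lookup = snp_table.set_index("snp_id")
        try:
            chrom = lookup.loc[snp_ids, "chrom"].to_numpy(dtype=object)
            pos = lookup.loc[snp_ids, "pos"].to_numpy(dtype=np.int64)
        except KeyError as exc:
            raise ParseError(f"snp_table missing ids from dosage TSV: {exc}") from exc
    else:
        chrom = np.array(["."] * len(snp_ids), dtype=object)
        pos = np.zeros(len(snp_ids), dtype=np.int64)
    return GenotypeMatrix(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        dosages=dosages,
        stratum=df["stratum"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# Phenotypes

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stratum": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype TSV missing columns: {missing}")
    if not df["status"].isin([0, 1]).all():
        raise ParseError("phenotype status must be 0 (control) or 1 (case)")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample id in phenotype TSV: {dup}")
    return df


# ---------------------------------------------------------------------------
# BED gene models

def write_bed(genes: pd.DataFrame, path) -> None:
    """Write gene models (internal 1-based inclusive) as BED 0-based half-open."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_bed(source) -> pd.DataFrame:
    """Parse BED text or a BED file into 1-based inclusive gene intervals.

    ``source`` may be a path or a string containing BED lines.  The fourth
    column is the gene id and must be unique.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    records = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ParseError(f"BED line {lineno}: expected >= 4 fields, got {len(parts)}")
        chrom, start_s, end_s, gene_id = parts[:4]
        try:
            start0, end0 = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"BED line {lineno}: non-integer coordinates") from exc
        if start0 < 0 or start0 >= end0:
            raise ParseError(f"BED line {lineno}: invalid interval [{start0}, {end0})")
        if gene_id in seen:
            raise ParseError(f"BED line {lineno}: duplicate gene id {gene_id}")
        seen.add(gene_id)
        strand = parts[5] if len(parts) >= 6 else "+"
        records.append((gene_id, chrom, start0 + 1, end0, strand))
    return pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    )


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt_records(source) -> list[tuple[str, str, list[str]]]:
    """Parse GMT text or file into (name, description, members) records.

    Duplicate member ids within a set are collapsed (first occurrence kept);
    duplicate set names are an error.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    records = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc = parts[0], parts[1]
        if name in seen:
            raise ParseError(f"GMT line {lineno}: duplicate set name {name}")
        seen.add(name)
        members = list(dict.fromkeys(m for m in parts[2:] if m))
        records.append((name, desc, members))
    return records
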