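"""Pre-flight checks on pipeline input files.

`validate_inputs` parses every file and cross-checks identifiers, returning
the full list of violations (not just the first) so a user can fix a fixture
in one pass.
"""

from __future__ import annotations

import os

from . import io as pio
from .errors import ParseError


def validate_inputs(
    genotypes_path,
    phenotypes_path,
    annotation_path,
    gmt_path,
) -> list[str]:
    """Check well-formedness and mutual consistency of the four inputs.

    Returns a list of human-readable violation strings; empty means clean.
    Unreadable files raise ``OSError``.
    """
    violations: list[str] = []

    for path in (genotypes_path, phenotypes_path, annotation_path, gmt_path):
        if not os.path.exists(os.fspath(path)):
            raise OSError(f"input file not found: {path}")

    genotypes = None
    try:
        if str(genotypes_path).endswith((".tsv", ".txt")):
            genotypes = pio.read_dosage_tsv(genotypes_path)
        else:
            genotypes = pio.read_vcf(genotypes_path)
    except (ParseError, ValueError, OSError) as exc:
        violations.append(f"genotypes: {exc}")

    pheno = None
    try:
        pheno = pio.read_phenotypes(phenotypes_path)
    except ParseError as exc:
        violations.append(f"phenotypes: {exc}")

    genes = None
    try:
        genes = pio.read_bed(annotation_path)
    except ParseError as exc:
        violations.append(f"annotation: {exc}")

    try:
        pio.read_gmt_records(gmt_path)
    except ParseError as exc:
        violations.append(f"pathways: {exc}")

    if genotypes is not None and pheno is not None:
        geno_ids = set(map(str, genotypes.sample_ids))
        pheno_ids = set(pheno["sample_id"])
        for sid in sorted(geno_ids - pheno_ids):
            violations.append(f"sample {sid} genotyped but missing from phenotypes")
        for sid in sorted(pheno_ids - geno_ids):
            violations.append(f"sample {sid} phenotyped but missing from genotypes")

    if genotypes is not None and genes is not None:
        snp_chroms = set(map(str, genotypes.chrom)) - {"."}
        gene_chroms = set(genes["chrom"])
        for chrom in sorted(snp_chroms - gene_chroms):
            violations.append(
                f"chromosome {chrom} carries SNPs but has no gene annotation"
            )

    return violations
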