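"""Simulate a multi-stratum case-control GWAS study and write it to disk.

Builds a small synthetic cohort — two nested case-control strata, 500
biallelic SNPs on a 100-gene genome, 10 curated pathways — and writes the
five fixture files (VCF, dosage TSV, phenotype TSV, BED, GMT) plus the
packaged positive-control gene sets.
"""

from pathlib import Path

from pathgwas import SimulationConfig, write_fixture

cfg = SimulationConfig(
    n_cases_per_stratum=(60, 50),
    n_controls_per_stratum=(180, 150),
    n_snps=500,
    n_genes=100,
    genes_per_chromosome=20,
    n_pathways=10,
    pathway_size_range=(10, 25),
    seed=1,
)

out = Path("scratch_example_study")
manifest = write_fixture(cfg, out)

print(f"wrote {len(manifest['files'])} files to {out}/")
for role, name in manifest["files"].items():
    print(f"  {role:12s} {name}")
# Every downstream stage reads exactly these formats, so this directory is a
# complete, self-contained input for the association and enrichment examples.
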