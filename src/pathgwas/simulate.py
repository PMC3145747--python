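"""Synthetic case-control GWAS studies with pathway-level genetic architecture.

The generator emulates the design the pipeline targets: several case-control
strata genotyped on a common biallelic SNP panel, genes laid out on a small
synthetic genome, curated gene sets, and a logistic disease model in which the
risk alleles are optionally clustered inside the genes of one or more "causal"
pathways.  Everything is a pure function of ``(config, seed)``.

Disease model
-------------
Each pool individual carries dosages ``g`` (Hardy-Weinberg, independent SNPs)
and covariates ``x = (age, pc1, pc2, pc3)``.  Case probability is

    P(case) = expit(b0 + log(OR) * sum(g_causal) + c . x)

with ``b0`` calibrated so that prevalence equals ``baseline_prevalence`` at
mean covariates and mean causal burden.  Strata are then filled to their
configured case/control counts by scanning a per-stratum population pool
(case-control sampling with rejection; the pool size caps the number of
draws at 1000x the requested total).
"""

from __future__ import annotations

import importlib.resources
import math
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as pio
from .errors import ConfigurationError, SimulationError

# fixed offsets for per-component random streams
_STREAM_GENO = 1
_STREAM_PHENO_COV = 2
_STREAM_PHENO_Y = 3
_STREAM_PATHWAYS = 4
_STREAM_CAUSAL = 5

POSITIVE_CONTROL_GMT = "positive_controls.gmt"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults emulate a four-stratum nested case-control design with a roughly
    1:3 case:control ratio, scaled to desk size, on a 10-chromosome synthetic
    genome of 300 genes and 2,000 independent SNPs.
    """

    n_cases_per_stratum: tuple[int, ...] = (66, 60, 25, 28)
    n_controls_per_stratum: tuple[int, ...] = (216, 156, 77, 72)
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 300
    genes_per_chromosome: int = 30
    gene_length_bp: int = 20_000
    intergenic_gap_bp: int = 100_000
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 50)
    causal_pathway_ids: tuple[str, ...] = ()
    causal_genes_per_pathway: int = 10
    odds_ratio_per_allele: float = 1.5
    baseline_prevalence: float = 0.2
    covariate_effects: tuple[float, float, float, float] = (0.02, 0.15, 0.10, 0.05)
    stratum_allele_drift: float = 0.0  # Balding-Nichols F; 0 = no structure
    seed: int = 0

    @property
    def n_strata(self) -> int:
        return len(self.n_cases_per_stratum)

    @property
    def stratum_labels(self) -> list[str]:
        return [f"stratum_{i + 1}" for i in range(self.n_strata)]

    def validate(self) -> None:
        if len(self.n_cases_per_stratum) != len(self.n_controls_per_stratum):
            raise ConfigurationError("case and control count lists differ in length")
        counts = (
            *self.n_cases_per_stratum,
            *self.n_controls_per_stratum,
            self.n_snps,
            self.n_genes,
            self.genes_per_chromosome,
            self.gene_length_bp,
            self.n_pathways,
            self.causal_genes_per_pathway,
        )
        if any(int(c) < 1 for c in counts):
            raise ConfigurationError("all counts must be >= 1")
        if self.intergenic_gap_bp < 0:
            raise ConfigurationError("intergenic_gap_bp must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.odds_ratio_per_allele <= 0:
            raise ConfigurationError("odds_ratio_per_allele must be > 0")
        if not (0 < self.baseline_prevalence < 1):
            raise ConfigurationError("baseline_prevalence must be in (0, 1)")
        plo, phi = self.pathway_size_range
        if plo > phi:
            raise ConfigurationError("pathway_size_range is inverted")
        if plo < 1 or phi > self.n_genes:
            raise ConfigurationError("pathway sizes must be in [1, n_genes]")
        if len(self.covariate_effects) != 4:
            raise ConfigurationError("covariate_effects must list (age, pc1, pc2, pc3)")
        known = {f"pathway_{i + 1:03d}" for i in range(self.n_pathways)}
        unknown = set(self.causal_pathway_ids) - known
        if unknown:
            raise ConfigurationError(f"causal_pathway_ids not generated: {sorted(unknown)}")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Annotation

def gen_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Lay out non-overlapping gene intervals chromosome by chromosome.

    Gene ``i`` within its chromosome occupies BED interval
    ``[i*(L+G), i*(L+G)+L)`` with configured length ``L`` and gap ``G``;
    internally coordinates are 1-based inclusive.  Strand alternates and is
    carried only for completeness (the mapping window is symmetric).
    """
    cfg.validate()
    step = cfg.gene_length_bp + cfg.intergenic_gap_bp
    records = []
    for i in range(cfg.n_genes):
        chrom_idx, slot = divmod(i, cfg.genes_per_chromosome)
        bed_start = slot * step
        records.append(
            (
                f"gene_{i + 1:04d}",
                f"chr{chrom_idx + 1}",
                bed_start + 1,
                bed_start + cfg.gene_length_bp,
                "+" if i % 2 == 0 else "-",
            )
        )
    return pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Genotypes

def _pool_sizes(cfg: SimulationConfig) -> list[int]:
    sizes = []
    for nca, nco in zip(cfg.n_cases_per_stratum, cfg.n_controls_per_stratum):
        need = max(nca / cfg.baseline_prevalence, nco / (1 - cfg.baseline_prevalence))
        cap = 1000 * (nca + nco)
        sizes.append(int(min(cap, math.ceil(1.5 * need) + 20)))
    return sizes


def _place_snps(cfg: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator):
    """Drop 60% of SNPs inside gene bodies and 40% in intergenic gaps."""
    n_genic = int(round(0.6 * cfg.n_snps))
    chroms = np.empty(cfg.n_snps, dtype=object)
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    gidx = rng.integers(0, len(genes), size=n_genic)
    chroms[:n_genic] = genes["chrom"].to_numpy(dtype=object)[gidx]
    starts = genes["start"].to_numpy()[gidx]
    ends = genes["end"].to_numpy()[gidx]
    pos[:n_genic] = rng.integers(starts, ends + 1)
    # intergenic: uniform within the gap following a random gene on its chromosome
    n_inter = cfg.n_snps - n_genic
    gidx2 = rng.integers(0, len(genes), size=n_inter)
    gap_start = genes["end"].to_numpy()[gidx2] + 1
    gap_len = max(cfg.intergenic_gap_bp, 1)
    chroms[n_genic:] = genes["chrom"].to_numpy(dtype=object)[gidx2]
    pos[n_genic:] = gap_start + rng.integers(0, gap_len, size=n_inter)
    order = np.lexsort((pos, np.array([_chrom_key(c) for c in chroms])))
    return chroms[order], pos[order]


def _chrom_key(chrom: str) -> int:
    digits = "".join(ch for ch in str(chrom) if ch.isdigit())
    return int(digits) if digits else 0


def gen_genotypes(cfg: SimulationConfig, genes: pd.DataFrame) -> pio.GenotypeMatrix:
    """Simulate Hardy-Weinberg dosages for the per-stratum population pools.

    Each SNP gets a minor-allele frequency drawn uniformly from
    ``cfg.maf_range``; dosages are Binomial(2, maf) per sample, independent
    across SNPs (no linkage disequilibrium).  With
    ``stratum_allele_drift > 0`` per-stratum frequencies are drawn from a
    Balding-Nichols beta around the ancestral value.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_GENO)
    chroms, pos = _place_snps(cfg, genes, rng)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    snp_ids = np.array([f"snp_{i + 1:06d}" for i in range(cfg.n_snps)], dtype=object)

    sizes = _pool_sizes(cfg)
    sample_ids, strata, blocks = [], [], []
    for s, (label, n_pool) in enumerate(zip(cfg.stratum_labels, sizes)):
        if cfg.stratum_allele_drift > 0:
            f = cfg.stratum_allele_drift
            a = maf * (1 - f) / f
            b = (1 - maf) * (1 - f) / f
            freq = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        else:
            freq = maf
        blocks.append(rng.binomial(2, freq, size=(n_pool, cfg.n_snps)).astype(np.int8))
        sample_ids.extend(f"{label}_s{j + 1:06d}" for j in range(n_pool))
        strata.extend([label] * n_pool)
    return pio.GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        snp_ids=snp_ids,
        chrom=chroms,
        pos=pos,
        dosages=np.concatenate(blocks, axis=0),
        stratum=np.array(strata, dtype=object),
        maf=maf,
    )


# ---------------------------------------------------------------------------
# Pathways

def gen_pathways(cfg: SimulationConfig, genes: pd.DataFrame) -> dict[str, list[str]]:
    """Sample ``n_pathways`` gene sets with sizes uniform in the configured range.

    Genes are drawn without replacement within a set; sets may overlap.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_PATHWAYS)
    gene_ids = genes["gene_id"].to_numpy(dtype=object)
    lo, hi = cfg.pathway_size_range
    sets: dict[str, list[str]] = {}
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"pathway_{i + 1:03d}"] = list(members)
    return sets


# ---------------------------------------------------------------------------
# Phenotypes

def _resolve_causal_snps(
    cfg: SimulationConfig,
    genotypes: pio.GenotypeMatrix,
    genes: pd.DataFrame,
    pathways: dict[str, list[str]],
) -> np.ndarray:
    """Pick ``causal_genes_per_pathway`` genes per causal pathway, one risk SNP
    (uniform among the gene-body SNPs) per gene."""
    if not cfg.causal_pathway_ids:
        return np.empty(0, dtype=np.intp)
    rng = _rng(cfg, _STREAM_CAUSAL)
    snp_chrom, snp_pos = genotypes.chrom, genotypes.pos
    by_gene: dict[str, np.ndarray] = {}
    for row in genes.itertuples(index=False):
        hits = np.flatnonzero(
            (snp_chrom == row.chrom) & (snp_pos >= row.start) & (snp_pos <= row.end)
        )
        if hits.size:
            by_gene[row.gene_id] = hits
    causal: list[int] = []
    for name in cfg.causal_pathway_ids:
        if name not in pathways:
            raise ConfigurationError(f"causal pathway {name} not in generated pathways")
        eligible = sorted(g for g in pathways[name] if g in by_gene)
        if len(eligible) < cfg.causal_genes_per_pathway:
            raise SimulationError(
                f"pathway {name}: only {len(eligible)} member genes contain SNPs, "
                f"need {cfg.causal_genes_per_pathway}"
            )
        chosen = rng.choice(np.array(eligible, dtype=object),
                            size=cfg.causal_genes_per_pathway, replace=False)
        for gene in chosen:
            causal.append(int(rng.choice(by_gene[gene])))
    return np.unique(np.array(causal, dtype=np.intp))


def gen_phenotypes(
    cfg: SimulationConfig,
    genotypes: pio.GenotypeMatrix,
    genes: pd.DataFrame,
    pathways: dict[str, list[str]],
) -> pd.DataFrame:
    """Assign case-control status under the logistic model and fill strata.

    Covariates: age ~ N(55 + 2*stratum_index, 8), pc1..pc3 ~ N(0, 1).  The
    intercept is calibrated so prevalence at mean covariates and mean causal
    burden equals ``baseline_prevalence``.  Each stratum's pool is scanned in
    order and the first ``n_cases`` cases / ``n_controls`` controls are kept;
    an exhausted pool raises :class:`SimulationError` naming the stratum.
    """
    cfg.validate()
    causal_idx = _resolve_causal_snps(cfg, genotypes, genes, pathways)
    beta_g = math.log(cfg.odds_ratio_per_allele)
    ceff = np.asarray(cfg.covariate_effects, dtype=float)

    rng_cov = _rng(cfg, _STREAM_PHENO_COV)
    rng_y = _rng(cfg, _STREAM_PHENO_Y)

    n = genotypes.n_samples
    stratum_index = np.zeros(n, dtype=np.intp)
    for s, label in enumerate(cfg.stratum_labels):
        stratum_index[genotypes.stratum == label] = s
    age = 55.0 + 2.0 * stratum_index + 8.0 * rng_cov.standard_normal(n)
    pcs = rng_cov.standard_normal((n, 3))

    mean_age = 55.0 + 2.0 * np.mean(np.arange(cfg.n_strata))
    if causal_idx.size and genotypes.maf is not None:
        mean_burden = float(2.0 * genotypes.maf[causal_idx].sum())
    elif causal_idx.size:
        mean_burden = float(
            np.mean(genotypes.dosages[:, causal_idx].clip(min=0).sum(axis=1))
        )
    else:
        mean_burden = 0.0
    intercept = (
        logit(cfg.baseline_prevalence)
        - beta_g * mean_burden
        - ceff[0] * mean_age  # pc means are zero
    )

    burden = (
        genotypes.dosages[:, causal_idx].clip(min=0).astype(float).sum(axis=1)
        if causal_idx.size
        else np.zeros(n)
    )
    eta = intercept + beta_g * burden + ceff[0] * age + pcs @ ceff[1:]
    status = (rng_y.random(n) < expit(eta)).astype(np.int8)

    keep_rows: list[int] = []
    keep_status: list[int] = []
    for s, label in enumerate(cfg.stratum_labels):
        rows = np.flatnonzero(genotypes.stratum == label)
        want_cases = cfg.n_cases_per_stratum[s]
        want_controls = cfg.n_controls_per_stratum[s]
        got_cases = got_controls = 0
        for r in rows:
            if status[r] == 1 and got_cases < want_cases:
                keep_rows.append(r)
                keep_status.append(1)
                got_cases += 1
            elif status[r] == 0 and got_controls < want_controls:
                keep_rows.append(r)
                keep_status.append(0)
                got_controls += 1
            if got_cases == want_cases and got_controls == want_controls:
                break
        if got_cases < want_cases or got_controls < want_controls:
            raise SimulationError(
                f"stratum {label}: pool of {rows.size} draws yielded "
                f"{got_cases}/{want_cases} cases and {got_controls}/{want_controls} "
                "controls; raise baseline_prevalence or the draw cap"
            )
    keep = np.array(keep_rows, dtype=np.intp)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids[keep],
            "status": np.array(keep_status, dtype=np.int8),
            "age": np.round(age[keep], 6),
            "pc1": np.round(pcs[keep, 0], 6),
            "pc2": np.round(pcs[keep, 1], 6),
            "pc3": np.round(pcs[keep, 2], 6),
            "stratum": genotypes.stratum[keep],
        }
    )


# ---------------------------------------------------------------------------
# Whole-study convenience and fixture writing

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genotypes: pio.GenotypeMatrix  # selected samples only, aligned to phenotypes
    phenotypes: pd.DataFrame
    genes: pd.DataFrame
    pathways: dict[str, list[str]]
    causal_snp_ids: list[str] = field(default_factory=list)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the full generator chain and subset genotypes to the sampled cohort."""
    genes = gen_annotation(cfg)
    pool = gen_genotypes(cfg, genes)
    pathways = gen_pathways(cfg, genes)
    pheno = gen_phenotypes(cfg, pool, genes, pathways)
    selected = pool.subset_samples(pheno["sample_id"].tolist())
    causal_idx = _resolve_causal_snps(cfg, pool, genes, pathways)
    return SimulatedStudy(
        config=cfg,
        genotypes=selected,
        phenotypes=pheno,
        genes=genes,
        pathways=pathways,
        causal_snp_ids=[str(s) for s in pool.snp_ids[causal_idx]],
    )


def positive_control_gmt_path() -> Path:
    """Filesystem path of the packaged positive-control gene sets."""
    return Path(importlib.resources.files("pathgwas") / "data" / POSITIVE_CONTROL_GMT)


def write_fixture(cfg: SimulationConfig, out_dir) -> dict:
    """Write a complete study fixture and a manifest describing it.

    Emits genotypes.vcf, dosages.tsv, phenotypes.tsv, genes.bed, pathways.gmt
    plus a copy of the packaged positive-control GMT, and manifest.txt with
    the configuration and file list.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    files = {
        "genotypes": "genotypes.vcf",
        "dosages": "dosages.tsv",
        "phenotypes": "phenotypes.tsv",
        "annotation": "genes.bed",
        "pathways": "pathways.gmt",
    }
    try:
        pio.write_vcf(study.genotypes, out / files["genotypes"])
        pio.write_dosage_tsv(study.genotypes, out / files["dosages"])
        pio.write_phenotypes(study.phenotypes, out / files["phenotypes"])
        pio.write_bed(study.genes, out / files["annotation"])
        pio.write_gmt(study.pathways, out / files["pathways"])
        shutil.copyfile(positive_control_gmt_path(), out / POSITIVE_CONTROL_GMT)
    except OSError as exc:
        raise SimulationError(f"failed writing fixture file under {out}: {exc}") from exc
    manifest = {
        "seed": cfg.seed,
        "files": files,
        "positive_controls": POSITIVE_CONTROL_GMT,
        "causal_snp_ids": study.causal_snp_ids,
        "config": asdict(cfg),
    }
    lines = [f"seed={cfg.seed}"]
    lines += [f"file.{k}={v}" for k, v in files.items()]
    lines.append(f"file.positive_controls={POSITIVE_CONTROL_GMT}")
    lines.append("causal_snp_ids=" + ",".join(study.causal_snp_ids))
    for k, v in asdict(cfg).items():
        lines.append(f"config.{k}={v}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
    return manifest
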