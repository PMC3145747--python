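"""SNP-to-gene assignment, gene-level statistics, ranking, and gene sets.

A SNP represents a gene when it lies within ``flank_bp`` (default 20 kb) of
the gene's transcript interval, inclusive on both ends and irrespective of
strand; one SNP may represent several overlapping genes.  Each gene's
statistic is the largest meta-analysis chi-square among its assigned SNPs,
and genes are ranked genome-wide by that value.  Pathways are intersected
with the ranked ("scoreable") genes and kept only when the eligible member
count lies within the configured size window (default 10-200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import PipelineError
from .io import read_bed, read_gmt_records

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 20_000
DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 200


def load_annotation(source) -> pd.DataFrame:
    """Load gene models from BED (path or text) into 1-based inclusive intervals."""
    genes = read_bed(source)
    if genes.empty:
        raise PipelineError("annotation contains no gene models")
    return genes


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Assign SNPs to genes within +/- ``flank_bp`` of the transcript.

    ``snps`` needs columns snp_id, chrom, pos (1-based).  Returns a
    (gene_id, snp_id) pair table; genes with no assigned SNP are absent.
    """
    if flank_bp < 0:
        raise PipelineError("flank_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        lo = max(row.start - flank_bp, 0)
        hi = row.end + flank_bp + 1  # half-open tree over 1-based inclusive window
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_id)
    pairs: list[tuple[str, str]] = []
    for snp in snps.itertuples(index=False):
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in tree.at(int(snp.pos)):
            pairs.append((iv.data, snp.snp_id))
    return pd.DataFrame(pairs, columns=["gene_id", "snp_id"])


def score_genes(assignment: pd.DataFrame, assoc: pd.DataFrame) -> pd.DataFrame:
    """Score each gene by its best assigned SNP.

    ``assoc`` is the meta-analysis table (snp_id, pos, chi2, p).  The gene
    statistic is the maximum chi-square; the representative SNP is the
    arg-max, ties broken by smallest position then lexicographic snp_id.
    Genes whose assigned SNPs all lack association records are dropped and
    logged (they were excluded upstream, e.g. monomorphic everywhere).
    """
    if assignment.empty:
        raise PipelineError("no SNP-gene assignments to score")
    merged = assignment.merge(assoc, on="snp_id", how="left")
    n_genes_in = merged["gene_id"].nunique()
    scored = merged.dropna(subset=["chi2"])
    dropped = n_genes_in - scored["gene_id"].nunique()
    if dropped:
        logger.warning("score_genes: dropped %d gene(s) with no scoreable SNP", dropped)
    if scored.empty:
        raise PipelineError("no gene has a scoreable SNP")
    # deterministic arg-max: chi2 desc, then pos asc, then snp_id asc
    scored = scored.sort_values(
        ["gene_id", "chi2", "pos", "snp_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = scored.groupby("gene_id", sort=True).first().reset_index()
    counts = scored.groupby("gene_id", sort=True).size().reset_index(name="snp_count")
    out = best.merge(counts, on="gene_id")
    out = out.rename(columns={"chi2": "score", "snp_id": "representative_snp",
                              "p": "representative_p"})
    cols = ["gene_id", "score", "representative_snp", "representative_p", "snp_count"]
    return out[cols]


@dataclass
class RankedGeneList:
    """Genes in descending order of their representative statistic."""

    gene_ids: np.ndarray
    stats: np.ndarray
    table: pd.DataFrame = field(repr=False)

    @property
    def N(self) -> int:
        return len(self.gene_ids)

    def __len__(self) -> int:
        return self.N


def rank_genes(scores: pd.DataFrame) -> RankedGeneList:
    """Sort gene scores descending; ties broken by gene_id (lexicographic)."""
    if scores.empty:
        raise PipelineError("rank_genes: empty score table")
    if scores["gene_id"].duplicated().any():
        raise PipelineError("rank_genes: duplicate gene ids")
    ordered = scores.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedGeneList(
        gene_ids=ordered["gene_id"].to_numpy(dtype=object),
        stats=ordered["score"].to_numpy(dtype=float),
        table=ordered,
    )


@dataclass
class GeneSet:
    name: str
    source: str
    members: list[str]
    eligible_members: list[str] | None = None

    @property
    def N_H(self) -> int:
        if self.eligible_members is None:
            raise PipelineError(f"gene set {self.name}: eligibility not yet computed")
        return len(self.eligible_members)


class GeneSetCollection:
    """Ordered collection of named gene sets."""

    def __init__(self, sets: list[GeneSet]):
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise PipelineError("duplicate gene-set names")
        self._sets = {s.name: s for s in sets}

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @classmethod
    def from_dict(cls, sets: dict, source: str = "custom") -> "GeneSetCollection":
        return cls([GeneSet(name=n, source=source, members=list(m))
                    for n, m in sets.items()])


def load_gmt(source, source_label: str = "custom") -> GeneSetCollection:
    """Parse GMT text or file; duplicate members collapse, duplicate names error."""
    records = read_gmt_records(source)
    return GeneSetCollection(
        [GeneSet(name=n, source=source_label or d, members=m) for n, d, m in records]
    )


def filter_pathways(
    sets: GeneSetCollection,
    ranked: RankedGeneList,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    exclude_genes: dict[str, list[str]] | None = None,
) -> GeneSetCollection:
    """Intersect sets with the ranked genes and keep those with
    ``min_size <= N_H <= max_size`` eligible members.

    ``exclude_genes`` maps set name -> gene ids to remove before the
    intersection (the overlap re-analysis hook).  Raises
    :class:`PipelineError` if nothing survives.
    """
    ranked_ids = set(ranked.gene_ids)
    exclude_genes = exclude_genes or {}
    surviving = []
    for gs in sets:
        drop = set(exclude_genes.get(gs.name, ()))
        eligible = [g for g in gs.members if g in ranked_ids and g not in drop]
        if min_size <= len(eligible) <= max_size:
            surviving.append(
                GeneSet(name=gs.name, source=gs.source,
                        members=list(gs.members), eligible_members=eligible)
            )
    if not surviving:
        raise PipelineError(
            f"no gene set has between {min_size} and {max_size} eligible members; "
            "check the size bounds against the annotation and ranked gene list"
        )
    return GeneSetCollection(surviving)


def write_gene_scores(scores: pd.DataFrame, path) -> None:
    """Gene-score TSV: gene_id, score, representative SNP, its p, SNP count."""
    scores.to_csv(path, sep="\t", index=False)
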