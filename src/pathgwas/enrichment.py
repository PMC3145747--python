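"""Weighted Kolmogorov-Smirnov pathway enrichment with a phenotype-permutation null.

Given genes ranked genome-wide by their representative SNP chi-square
``r_(1) >= r_(2) >= ... >= r_(N)``, a pathway S with N_H eligible members gets
a running sum that walks the ranked list and accumulates

    + |r_j|^p / N_R      when gene j is in S,  N_R = sum_{g in S} |r_g|^p,
    - 1 / (N - N_H)      otherwise.

The enrichment score ES is the maximum of the running sum (maximum positive
deviation; enrichment at the top of the list only).  Significance comes from
permuting case-control labels within each stratum and re-running the whole
chain (per-SNP association, meta-analysis, gene scoring, ranking, ES) K
times; pathway membership and the size filter stay frozen at their
observed-data values.  Each pathway's ES is standardised by the mean and
sample standard deviation of its own permutation scores (NES), the nominal
p-value is the add-one permutation tail ``(1 + #{ES_k >= ES}) / (K + 1)``,
and the FDR is the GSEA-style permutation FDR: the pooled tail fraction of
normalised permutation scores over the tail fraction of observed NES, capped
at one and monotonised so FDR never increases with NES.  Benjamini-Hochberg
on the nominal p-values is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association as assoc_mod
from .errors import DegenerateSetError, PipelineError
from .io import DEFAULT_COVARIATES, GenotypeMatrix
from .mapping import (
    DEFAULT_FLANK_BP,
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    GeneSetCollection,
    RankedGeneList,
    filter_pathways,
    load_annotation,
    load_gmt,
    map_snps_to_genes,
    rank_genes,
    score_genes,
)

logger = logging.getLogger(__name__)

_PROGRESS_INTERVAL = 10


@dataclass(frozen=True)
class EnrichmentParams:
    """Tuning knobs for the enrichment stage.

    weight_p
        Exponent on the gene statistic in the running-sum increment; 1 is the
        weighted statistic used throughout, 0 recovers the classic
        (unweighted) Kolmogorov-Smirnov statistic.
    n_permutations
        Number K of phenotype permutations for the null.
    null_mode
        ``"exact"`` re-fits the full per-SNP logistic model in every
        permutation (reference); ``"score"`` uses the efficient score
        statistic from a covariate-only fit, two orders of magnitude faster
        and applied to observed and permuted data alike so the permutation
        test stays exchangeable.
    fdr_method
        ``"permutation"`` (GSEA-style, default) or ``"bh"``
        (Benjamini-Hochberg on nominal p-values).
    """

    weight_p: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE
    flank_bp: int = DEFAULT_FLANK_BP
    null_mode: str = "exact"
    fdr_method: str = "permutation"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise PipelineError("n_permutations must be >= 1")
        if self.weight_p < 0:
            raise PipelineError("weight_p must be >= 0")
        if self.min_size < 1 or self.min_size > self.max_size:
            raise PipelineError("invalid pathway size window")
        if self.flank_bp < 0:
            raise PipelineError("flank_bp must be >= 0")
        if self.null_mode not in ("exact", "score"):
            raise PipelineError(f"unknown null_mode {self.null_mode!r}")
        if self.fdr_method not in ("permutation", "bh"):
            raise PipelineError(f"unknown fdr_method {self.fdr_method!r}")


# ---------------------------------------------------------------------------
# Enrichment score

def _running_sum(stats_sorted: np.ndarray, member_mask: np.ndarray, weight_p: float):
    rp = np.abs(stats_sorted) ** weight_p
    n_r = rp[member_mask].sum()
    n = stats_sorted.size
    n_h = int(member_mask.sum())
    if n_h == 0 or n_h == n:
        raise DegenerateSetError(f"gene set covers {n_h} of {n} ranked genes")
    if n_r <= 0:
        raise DegenerateSetError("all member gene statistics are zero")
    inc = np.where(member_mask, rp / n_r, -1.0 / (n - n_h))
    return np.cumsum(inc)


def compute_es(ranked: RankedGeneList, set_members, weight_p: float = 1.0):
    """Enrichment score of one gene set against a ranked gene list.

    Returns ``(es, leading_edge)`` where the leading edge lists the member
    genes at or before the (first) position where the running sum peaks,
    in ranked order.
    """
    members = set(set_members)
    mask = np.array([g in members for g in ranked.gene_ids], dtype=bool)
    cum = _running_sum(ranked.stats, mask, weight_p)
    peak = int(np.argmax(cum))
    es = float(cum[peak])
    leading = [g for g, m in zip(ranked.gene_ids[: peak + 1], mask[: peak + 1]) if m]
    return es, leading


def _es_batch(stats_sorted: np.ndarray, masks_sorted: np.ndarray, weight_p: float):
    """Vectorised ES over P pathways sharing one ranked list.

    ``masks_sorted`` is (P, N) boolean in ranked order.  Degenerate rows
    (empty, full, or zero total weight) yield ES 0 and a False entry in the
    returned validity vector.
    """
    p_count, n = masks_sorted.shape
    rp = np.abs(stats_sorted) ** weight_p
    n_h = masks_sorted.sum(axis=1)
    n_r = masks_sorted @ rp
    ok = (n_h > 0) & (n_h < n) & (n_r > 0)
    n_r_safe = np.where(ok, n_r, 1.0)
    miss = np.where(n_h < n, -1.0 / np.maximum(n - n_h, 1), 0.0)
    inc = np.where(masks_sorted, rp[None, :] / n_r_safe[:, None], miss[:, None])
    cum = np.cumsum(inc, axis=1)
    es = np.where(ok, cum.max(axis=1), 0.0)
    return es, ok


def _as_collection(sets) -> GeneSetCollection:
    if isinstance(sets, GeneSetCollection):
        return sets
    if isinstance(sets, dict):
        return GeneSetCollection.from_dict(sets, source="synthetic")
    return load_gmt(sets)


# ---------------------------------------------------------------------------
# Permutation machinery

class _Chain:
    """Observed-data context reused by every permutation replicate.

    Freezes the SNP-gene assignment, the scoreable gene list and the
    eligible pathway membership, and keeps the per-stratum design matrices
    so a replicate only has to swap in permuted labels and recompute
    statistics.
    """

    def __init__(self, genotypes, pheno, genes, sets: GeneSetCollection,
                 params: EnrichmentParams, covariates=DEFAULT_COVARIATES):
        self.params = params
        self.mode = "score" if params.null_mode == "score" else "wald"
        self.strata = assoc_mod.prepare_strata(genotypes, pheno, covariates)
        self.genotypes = genotypes
        observed = assoc_mod.run_gwas(
            genotypes, pheno, covariates, mode=self.mode, strata=self.strata
        )
        self.observed_gwas = observed
        assignment = map_snps_to_genes(observed.meta, genes, params.flank_bp)
        self.gene_scores = score_genes(assignment, observed.meta)
        self.ranked = rank_genes(self.gene_scores)
        self.filtered = filter_pathways(
            sets, self.ranked, params.min_size, params.max_size
        )
        self.pathway_names = self.filtered.names

        # gene index space: observed scoreable genes, lexicographic order
        self.gene_ids = np.sort(self.gene_scores["gene_id"].to_numpy(dtype=object))
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        snp_col = {s: j for j, s in enumerate(genotypes.snp_ids)}
        self._observed_chi2 = np.full(genotypes.n_snps, np.nan)
        obs_cols = observed.meta["snp_id"].map(snp_col).to_numpy(dtype=np.intp)
        self._observed_chi2[obs_cols] = observed.meta["chi2"].to_numpy()
        grouped = assignment.sort_values(["gene_id", "snp_id"], kind="mergesort")
        grouped = grouped[grouped["gene_id"].isin(gene_pos)]
        cols = grouped["snp_id"].map(snp_col).to_numpy(dtype=np.intp)
        gidx = grouped["gene_id"].map(gene_pos).to_numpy(dtype=np.intp)
        order = np.argsort(gidx, kind="stable")
        self._pair_cols = cols[order]
        starts = np.searchsorted(gidx[order], np.arange(len(self.gene_ids)))
        self._offsets = starts
        self._masks = np.zeros((len(self.filtered), len(self.gene_ids)), dtype=bool)
        for i, name in enumerate(self.pathway_names):
            for g in self.filtered[name].eligible_members:
                self._masks[i, gene_pos[g]] = True

    def _chi2_vector(self, y_by_label: dict[str, np.ndarray] | None) -> np.ndarray:
        S = self.genotypes.n_snps
        nk = len(self.strata)
        betas = np.full((S, nk), np.nan)
        ses = np.full((S, nk), np.nan)
        for k, data in enumerate(self.strata):
            y = data.y if y_by_label is None else y_by_label[data.label]
            betas[:, k], ses[:, k] = assoc_mod._stratum_fit(data, y, self.mode)
        chi2 = assoc_mod._meta_vectorized(betas, ses)[3]
        return chi2

    def _gene_stats(self, chi2: np.ndarray) -> np.ndarray:
        vals = chi2[self._pair_cols]
        vals = np.where(np.isfinite(vals), vals, -np.inf)
        scores = np.maximum.reduceat(vals, self._offsets)
        # genes whose offset slice is empty or all-excluded: neutral zero
        empty = self._offsets == np.append(self._offsets[1:], len(self._pair_cols))
        scores = np.where(empty | ~np.isfinite(scores), 0.0, scores)
        return scores

    def _es_from_gene_stats(self, scores: np.ndarray) -> np.ndarray:
        order = np.lexsort((self.gene_ids, -scores))
        es, ok = _es_batch(scores[order], self._masks[:, order], self.params.weight_p)
        if not ok.all():
            logger.warning(
                "degenerate gene set(s) in a replicate; ES recorded as 0: %s",
                [n for n, good in zip(self.pathway_names, ok) if not good],
            )
        return es

    def replicate_es(self, seed: int) -> np.ndarray:
        y_perm = assoc_mod.permuted_status_by_stratum(self.strata, seed)
        return self._es_from_gene_stats(self._gene_stats(self._chi2_vector(y_perm)))

    def observed_es(self) -> np.ndarray:
        return self._es_from_gene_stats(self._gene_stats(self._observed_chi2))


def permutation_null(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    annotation,
    sets,
    params: EnrichmentParams,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """K permutation enrichment scores per surviving pathway.

    Returns a DataFrame indexed by pathway name with K columns; deterministic
    in ``params.seed``.
    """
    params.validate()
    genes = annotation if isinstance(annotation, pd.DataFrame) else load_annotation(annotation)
    collection = _as_collection(sets)
    chain = _Chain(genotypes, pheno, genes, collection, params, covariates)
    perm = _run_permutations(chain, params)
    return pd.DataFrame(perm, index=chain.pathway_names)


def _perm_seeds(params: EnrichmentParams) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(97,)))
    return rng.integers(0, 2**31 - 1, size=params.n_permutations)


def _run_permutations(chain: _Chain, params: EnrichmentParams) -> np.ndarray:
    seeds = _perm_seeds(params)
    perm = np.empty((len(chain.pathway_names), params.n_permutations))
    for k, seed in enumerate(seeds):
        perm[:, k] = chain.replicate_es(int(seed))
        if (k + 1) % _PROGRESS_INTERVAL == 0:
            logger.info("permutation %d / %d", k + 1, params.n_permutations)
    return perm


# ---------------------------------------------------------------------------
# Normalisation, p-values, FDR

def nominal_p(es_obs: float, perm_es: np.ndarray) -> float:
    """Add-one one-sided permutation p-value: (1 + #{ES_k >= ES}) / (K + 1)."""
    perm_es = np.asarray(perm_es, dtype=float)
    if perm_es.size < 1:
        raise PipelineError("nominal_p needs at least one permutation value")
    return float((1 + int((perm_es >= es_obs).sum())) / (perm_es.size + 1))


def normalize_es(es_obs: float, perm_es: np.ndarray):
    """Standardise ES by its own permutation null: NES = (ES - mean) / sd.

    Uses the sample standard deviation (K-1 denominator) and applies the same
    transform to the permutation values.  Zero spread returns ``(nan, nan
    array)``; callers exclude such pathways from the FDR.
    """
    perm_es = np.asarray(perm_es, dtype=float)
    if perm_es.size < 2:
        raise PipelineError("normalize_es needs at least two permutation values")
    mu = perm_es.mean()
    sd = perm_es.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        return float("nan"), np.full_like(perm_es, np.nan)
    return float((es_obs - mu) / sd), (perm_es - mu) / sd


def compute_fdr(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """GSEA-style permutation FDR over normalised scores.

    For each observed NES* the raw ratio is
    ``mean(pooled permutation NES >= NES*) / mean(observed NES >= NES*)``
    capped at 1, then monotonised (each pathway takes the minimum raw value
    over itself and every lower-NES threshold) so FDR is non-increasing in
    NES.  Pathways with undefined NES must be excluded beforehand.
    """
    nes_obs = np.asarray(nes_obs, dtype=float)
    if nes_obs.size == 0 or not np.isfinite(nes_obs).all():
        raise PipelineError("compute_fdr requires finite observed NES values")
    pooled = np.asarray(nes_perm, dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise PipelineError("compute_fdr requires permutation NES values")
    raw = np.empty_like(nes_obs)
    for i, t in enumerate(nes_obs):
        numer = (pooled >= t).mean()
        denom = (nes_obs >= t).mean()  # >= 1/P, includes pathway i itself
        raw[i] = min(1.0, numer / denom)
    order = np.argsort(-nes_obs, kind="stable")
    q_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
    fdr = np.empty_like(raw)
    fdr[order] = q_sorted
    return fdr


def _bh_fdr(p_values: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_values, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# End-to-end

def run_enrichment(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    annotation,
    gmt,
    params: EnrichmentParams | None = None,
    exclude_genes: dict[str, list[str]] | None = None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Observed chain once, permutation chain K times, then p / NES / FDR.

    ``annotation`` is a gene-model DataFrame or BED source; ``gmt`` a
    :class:`GeneSetCollection` or GMT source.  ``exclude_genes`` removes the
    named genes from specific sets before eligibility filtering (the
    shared-gene overlap re-analysis).  Output rows are sorted by nominal
    p-value (ties by pathway name) and the whole table is a pure function of
    the inputs and ``params.seed``.
    """
    params = params or EnrichmentParams()
    params.validate()
    genes = annotation if isinstance(annotation, pd.DataFrame) else load_annotation(annotation)
    collection = _as_collection(gmt)
    chain = _Chain(genotypes, pheno, genes, collection, params, covariates)
    if exclude_genes:
        chain.filtered = filter_pathways(
            collection, chain.ranked, params.min_size, params.max_size,
            exclude_genes=exclude_genes,
        )
        chain.pathway_names = chain.filtered.names
        gene_pos = {g: i for i, g in enumerate(chain.gene_ids)}
        chain._masks = np.zeros((len(chain.filtered), len(chain.gene_ids)), dtype=bool)
        for i, name in enumerate(chain.pathway_names):
            for g in chain.filtered[name].eligible_members:
                chain._masks[i, gene_pos[g]] = True

    es_obs = chain.observed_es()
    perm = _run_permutations(chain, params)

    names = chain.pathway_names
    p_nom = np.array([nominal_p(es_obs[i], perm[i]) for i in range(len(names))])
    if params.n_permutations >= 2:
        nes = np.empty(len(names))
        nes_perm = np.empty_like(perm)
        for i in range(len(names)):
            nes[i], nes_perm[i] = normalize_es(es_obs[i], perm[i])
    else:
        nes = np.full(len(names), np.nan)
        nes_perm = np.full_like(perm, np.nan)

    fdr = np.full(len(names), np.nan)
    if params.fdr_method == "bh" or params.n_permutations < 2:
        if params.fdr_method != "bh":
            logger.warning("K < 2: NES undefined, falling back to Benjamini-Hochberg FDR")
        fdr = _bh_fdr(p_nom)
    else:
        defined = np.isfinite(nes)
        if (~defined).any():
            logger.warning(
                "pathways with undefined NES excluded from FDR: %s",
                [n for n, d in zip(names, defined) if not d],
            )
        if defined.any():
            fdr[defined] = compute_fdr(nes[defined], nes_perm[defined])

    # leading edge with representative SNP detail
    score_lookup = chain.gene_scores.set_index("gene_id")
    leading_edges = []
    for name in names:
        _, leading = compute_es(
            chain.ranked, chain.filtered[name].eligible_members, params.weight_p
        )
        parts = [
            f"{g}:{score_lookup.loc[g, 'representative_snp']}:"
            f"{score_lookup.loc[g, 'representative_p']:.3g}"
            for g in leading
        ]
        leading_edges.append("|".join(parts))

    out = pd.DataFrame(
        {
            "pathway": names,
            "source": [chain.filtered[n].source for n in names],
            "n_genes": [chain.filtered[n].N_H for n in names],
            "ES": es_obs,
            "NES": nes,
            "p_nominal": p_nom,
            "FDR": fdr,
            "leading_edge": leading_edges,
        }
    )
    out = out.sort_values(["p_nominal", "pathway"], kind="mergesort").reset_index(drop=True)
    return out


def write_pathway_results(results: pd.DataFrame, path) -> None:
    """Pathway-results TSV: source, pathway, gene count, FDR, p, leading edge."""
    cols = ["source", "pathway", "n_genes", "FDR", "p_nominal", "ES", "NES", "leading_edge"]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
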