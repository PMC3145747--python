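"""Enrichment score, permutation null, NES, nominal p and permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathgwas import (
    EnrichmentParams,
    SimulationConfig,
    compute_es,
    compute_fdr,
    nominal_p,
    normalize_es,
    permutation_null,
    run_enrichment,
    simulate_study,
)
from pathgwas.enrichment import _es_batch
from pathgwas.errors import DegenerateSetError, PipelineError

from .conftest import es_bruteforce, make_ranked, random_es_instance, unweighted_ks_es


class TestEnrichmentScore:
    def test_top_gene_member(self):
        ranked = make_ranked([5.0, 3.0, 2.0], ["g1", "g2", "g3"])
        es, leading = compute_es(ranked, {"g1"})
        assert es == pytest.approx(1.0)
        assert leading == ["g1"]

    def test_bottom_gene_member(self):
        ranked = make_ranked([5.0, 3.0, 2.0], ["g1", "g2", "g3"])
        es, leading = compute_es(ranked, {"g3"})
        assert es == pytest.approx(0.0)
        assert leading == ["g3"]

    def test_member_increments_are_normalized(self):
        # the running sum returns to zero at the end of the list
        stats, flags = random_es_instance(np.random.default_rng(0))
        from pathgwas.enrichment import _running_sum

        cum = _running_sum(stats, flags, weight_p=1.0)
        assert cum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            stats, flags = random_es_instance(rng)
            gene_ids = [f"g{i:04d}" for i in range(len(stats))]
            ranked = make_ranked(stats, gene_ids)
            members = {g for g, m in zip(gene_ids, flags) if m}
            es, _ = compute_es(ranked, members, weight_p=1.0)
            assert es == pytest.approx(es_bruteforce(stats, flags, 1.0), abs=1e-12)

    def test_weight_zero_is_classic_ks(self):
        rng = np.random.default_rng(5)
        stats, flags = random_es_instance(rng)
        gene_ids = [f"g{i:04d}" for i in range(len(stats))]
        es, _ = compute_es(make_ranked(stats, gene_ids),
                           {g for g, m in zip(gene_ids, flags) if m}, weight_p=0.0)
        assert es == pytest.approx(unweighted_ks_es(flags), abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = make_ranked([5.0, 3.0, 2.0], ["g1", "g2", "g3"])
        with pytest.raises(DegenerateSetError):
            compute_es(ranked, set())
        with pytest.raises(DegenerateSetError):
            compute_es(ranked, {"g1", "g2", "g3"})
        zeros = make_ranked([1.0, 0.0, 0.0], ["g1", "g2", "g3"])
        with pytest.raises(DegenerateSetError):
            compute_es(zeros, {"g2", "g3"})

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(77)
        stats, _ = random_es_instance(rng, n_max=40)
        n = len(stats)
        masks = np.zeros((5, n), dtype=bool)
        for i in range(5):
            masks[i, rng.choice(n, size=rng.integers(1, n), replace=False)] = True
        es_b, ok = _es_batch(stats, masks, 1.0)
        gene_ids = [f"g{i:04d}" for i in range(n)]
        ranked = make_ranked(stats, gene_ids)
        for i in range(5):
            if ok[i]:
                es_s, _ = compute_es(ranked, {g for g, m in zip(gene_ids, masks[i]) if m})
                assert es_b[i] == pytest.approx(es_s, abs=1e-12)

    def test_leading_edge_precedes_peak(self):
        rng = np.random.default_rng(8)
        stats, flags = random_es_instance(rng)
        gene_ids = [f"g{i:04d}" for i in range(len(stats))]
        ranked = make_ranked(stats, gene_ids)
        members = {g for g, m in zip(gene_ids, flags) if m}
        es, leading = compute_es(ranked, members)
        assert set(leading) <= members
        assert leading == [g for g in ranked.gene_ids if g in members][: len(leading)]


class TestNominalP:
    def test_direct_count(self):
        assert nominal_p(0.8, [0.9, 0.7, 0.5, 0.3]) == pytest.approx(0.4)

    def test_add_one_floor(self):
        assert nominal_p(1.0, np.zeros(999)) == pytest.approx(1 / 1000)

    def test_ceiling_is_one(self):
        assert nominal_p(-0.5, np.linspace(0, 1, 99)) == pytest.approx(1.0)


class TestNES:
    def test_arithmetic(self):
        # permutation values with mean 0.5, sample sd 0.1
        nes, nperm = normalize_es(0.7, [0.4, 0.5, 0.6])
        assert nes == pytest.approx(2.0)
        assert nperm.mean() == pytest.approx(0.0, abs=1e-12)

    def test_centering(self):
        nes, _ = normalize_es(0.5, [0.3, 0.5, 0.7])
        assert nes == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            perm = rng.normal(0.4, 0.15, size=rng.integers(3, 30))
            obs = rng.normal(0.5, 0.2)
            nes, nperm = normalize_es(obs, perm)
            assert nes == pytest.approx(
                (obs - perm.mean()) / perm.std(ddof=1), abs=1e-12
            )
            assert np.allclose(nperm, (perm - perm.mean()) / perm.std(ddof=1))

    def test_zero_spread_flagged(self):
        nes, nperm = normalize_es(0.5, [0.2, 0.2, 0.2])
        assert np.isnan(nes) and np.isnan(nperm).all()


class TestPermutationFdr:
    def test_hand_enumerated_toy(self):
        nes_obs = np.array([2.0, 1.0, 0.5])
        nes_perm = np.array(
            [[1.5, 0.5, -0.5, 0.2], [0.8, -0.2, 1.2, 0.1], [0.3, 0.4, -0.1, 0.6]]
        )
        fdr = compute_fdr(nes_obs, nes_perm)
        # thresholds 2.0, 1.0, 0.5 over the 12 pooled values
        assert fdr[0] == pytest.approx(0.0)
        assert fdr[1] == pytest.approx((2 / 12) / (2 / 3))
        assert fdr[2] == pytest.approx((5 / 12) / 1.0)

    def test_empty_numerator_gives_zero(self):
        fdr = compute_fdr(np.array([3.0]), np.array([[0.1, 0.2, -0.3]]))
        assert fdr[0] == 0.0

    def test_capped_at_one_and_monotone(self):
        rng = np.random.default_rng(11)
        nes_obs = rng.normal(size=25)
        nes_perm = rng.normal(size=(25, 40))
        fdr = compute_fdr(nes_obs, nes_perm)
        assert ((fdr >= 0) & (fdr <= 1)).all()
        order = np.argsort(-nes_obs)
        assert (np.diff(fdr[order]) >= -1e-12).all()  # non-increasing in NES

    def test_null_observations_have_high_fdr(self):
        # observed NES drawn from the same distribution as the permutations
        rng = np.random.default_rng(42)
        nes_perm = rng.normal(size=(60, 100))
        nes_obs = rng.normal(size=60)
        fdr = compute_fdr(nes_obs, nes_perm)
        assert np.median(fdr) >= 0.5


NULL_CFG = SimulationConfig(
    n_cases_per_stratum=(150,),
    n_controls_per_stratum=(150,),
    n_snps=600,
    n_genes=120,
    genes_per_chromosome=20,
    n_pathways=20,
    pathway_size_range=(10, 30),
    covariate_effects=(0.0, 0.0, 0.0, 0.0),
    odds_ratio_per_allele=1.0,
    seed=19,
)


class TestPermutationNull:
    def test_deterministic_matrix(self, tiny_study):
        params = EnrichmentParams(n_permutations=2, seed=33, min_size=5)
        kw = dict(
            genotypes=tiny_study.genotypes, pheno=tiny_study.phenotypes,
            annotation=tiny_study.genes, sets=tiny_study.pathways, params=params,
        )
        a = permutation_null(**kw)
        b = permutation_null(**kw)
        pd.testing.assert_frame_equal(a, b)
        assert a.shape[1] == 2

    def test_observed_es_within_null_span(self):
        study = simulate_study(NULL_CFG)
        params = EnrichmentParams(n_permutations=100, seed=3, null_mode="score")
        res = run_enrichment(study.genotypes, study.phenotypes, study.genes,
                             study.pathways, params)
        perm = permutation_null(study.genotypes, study.phenotypes, study.genes,
                                study.pathways, params)
        inside = 0
        for _, row in res.iterrows():
            lo, hi = perm.loc[row["pathway"]].min(), perm.loc[row["pathway"]].max()
            inside += lo <= row["ES"] <= hi
        assert inside >= 0.9 * len(res)


class TestRunEnrichment:
    def test_causal_pathway_ranks_first(self):
        cfg = SimulationConfig(
            n_cases_per_stratum=(150,), n_controls_per_stratum=(300,),
            n_snps=600, n_genes=80, genes_per_chromosome=20,
            n_pathways=12, pathway_size_range=(10, 25),
            causal_pathway_ids=("pathway_003",), causal_genes_per_pathway=8,
            odds_ratio_per_allele=2.0, seed=7,
        )
        study = simulate_study(cfg)
        params = EnrichmentParams(n_permutations=50, seed=11, min_size=5)
        res = run_enrichment(study.genotypes, study.phenotypes, study.genes,
                             study.pathways, params)
        assert res.iloc[0]["pathway"] == "pathway_003"
        assert res.iloc[0]["p_nominal"] == res["p_nominal"].min()

    def test_excluding_leading_edge_does_not_raise_es(self, tiny_study):
        params = EnrichmentParams(n_permutations=5, seed=2, min_size=5)
        base = run_enrichment(tiny_study.genotypes, tiny_study.phenotypes,
                              tiny_study.genes, tiny_study.pathways, params)
        target = base.iloc[0]
        leading = [part.split(":")[0] for part in target["leading_edge"].split("|") if part]
        assert leading
        redone = run_enrichment(
            tiny_study.genotypes, tiny_study.phenotypes, tiny_study.genes,
            tiny_study.pathways,
            EnrichmentParams(n_permutations=5, seed=2, min_size=1),
            exclude_genes={target["pathway"]: leading},
        )
        if target["pathway"] in set(redone["pathway"]):
            new_es = redone.set_index("pathway").loc[target["pathway"], "ES"]
            assert new_es <= target["ES"] + 1e-12

    def test_single_permutation_smoke(self, tiny_study):
        params = EnrichmentParams(n_permutations=1, seed=4, min_size=5)
        res = run_enrichment(tiny_study.genotypes, tiny_study.phenotypes,
                             tiny_study.genes, tiny_study.pathways, params)
        assert ((res["FDR"] >= 0) & (res["FDR"] <= 1)).all()
        assert ((res["p_nominal"] > 0) & (res["p_nominal"] <= 1)).all()
        assert (res["ES"] <= 1).all()

    def test_fast_and_exact_modes_agree_on_ranking(self, tiny_study):
        kw = dict(
            genotypes=tiny_study.genotypes, pheno=tiny_study.phenotypes,
            annotation=tiny_study.genes, gmt=tiny_study.pathways,
        )
        exact = run_enrichment(
            params=EnrichmentParams(n_permutations=10, seed=5, min_size=5), **kw
        )
        fast = run_enrichment(
            params=EnrichmentParams(n_permutations=10, seed=5, min_size=5,
                                    null_mode="score"), **kw
        )
        merged = exact.merge(fast, on="pathway", suffixes=("_e", "_f"))
        rho = sps.spearmanr(merged["ES_e"], merged["ES_f"]).statistic
        assert rho > 0.8

    def test_bh_fdr_alternative(self, tiny_study):
        params = EnrichmentParams(n_permutations=10, seed=6, min_size=5,
                                  fdr_method="bh")
        res = run_enrichment(tiny_study.genotypes, tiny_study.phenotypes,
                             tiny_study.genes, tiny_study.pathways, params)
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(res["p_nominal"], method="fdr_bh")[1]
        assert np.allclose(res["FDR"], expected)

    def test_invalid_params_rejected(self, tiny_study):
        with pytest.raises(PipelineError):
            EnrichmentParams(n_permutations=0).validate()
        with pytest.raises(PipelineError):
            EnrichmentParams(weight_p=-1).validate()
        with pytest.raises(PipelineError):
            EnrichmentParams(null_mode="bogus").validate()
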