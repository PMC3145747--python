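# Methods

## The problem

Single-marker GWAS tests are underpowered for diseases whose genetic
architecture is spread across many functionally related loci of modest
effect. `pathgwas` implements the pathway-level alternative for case-control
data: rank every gene in the genome by the strength of its best local SNP
association, then ask whether the members of a curated gene set concentrate
near the top of that ranking more than chance allows, with "chance"
defined by permuting case-control labels and re-running the whole analysis.

## Per-SNP association

Within each case-control stratum `s`, SNP `j` is fit with an additive
multivariable logistic regression

    logit P(y=1) = b0 + beta_j g_j + c' x,

where `g_j` is the 0/1/2 allele dosage and `x` the covariates (age and the
first three genetic principal components by default; arbitrary extra columns
are accepted, which also covers sensitivity adjustments such as the parent
study's own case status).  Missing dosages are dropped per SNP
(complete-case within stratum).  The Wald estimate `(beta_js, se_js)` feeds
a fixed-effect inverse-variance meta-analysis across strata:

    w_s = 1/se_js^2,  beta_j = sum(w_s beta_js)/sum(w_s),
    se_j = sum(w_s)^{-1/2},  chi2_j = (beta_j/se_j)^2,

with the p-value from the 1-df chi-square distribution.  Strata in which a
SNP is monomorphic, separated, or non-convergent are flagged and skipped;
SNPs unusable in every stratum are excluded and logged.

The solver is a Newton/IRLS iteration (tolerance 1e-8 on the coefficient
step, at most 50 iterations, linear predictor clipped at ±30) batched over
SNPs: the covariate block of the design matrix is shared by all SNPs, so
each iteration assembles all Hessians with a few dense matrix products.
This is what makes a permutation null that re-fits every SNP in every
stratum hundreds of times feasible on one CPU; `statsmodels` GLM fits agree
with the batched solver to well below 1e-6 and serve as the independent
reference in the tests.

### Score-statistic fast mode

`EnrichmentParams(null_mode="score")` replaces the per-SNP Newton fits with
the efficient score test at the covariate-only fit: one small logistic fit
per stratum per permutation, then for each SNP

    U_j = g_j'(y - mu0),   V_j = g_j'W g_j - g_j'W Z (Z'WZ)^{-1} Z'W g_j,
    chi2_j = U_j^2 / V_j,

with the one-step estimate `beta = U/V`, `se = V^{-1/2}` passed through the
same meta-analysis.  Observed and permuted data use the same statistic, so
the permutation test remains an exact exchangeability argument; the score
and Wald chi-squares are asymptotically equivalent and empirically near
perfectly rank-correlated at the sample sizes involved.  The exact Wald
mode is the default and the reference; score mode is roughly 20x faster and
is what makes the larger calibration and power simulations in the test
suite practical at full size.  Score mode requires complete dosages (the
simulator emits none missing); with missing data use the exact mode.

## Gene scoring and ranking

A SNP represents gene `g` when it lies within 20 kb (configurable) of the
transcript interval, inclusive at both boundaries and ignoring strand — the
window is symmetric, so strand cannot matter.  One SNP may represent several
overlapping genes (adjacent genes share flanking SNPs).  Gene `g`'s
statistic `r_g` is the maximum meta chi-square over its assigned SNPs; the
representative SNP is the arg-max with ties broken by smallest position then
lexicographic SNP id.  Genes are ranked by `r_g` descending, ties broken by
gene id, making the ranking bit-stable across platforms.  Genes with no
scoreable SNP are dropped before ranking.

Taking the max over a window favours long, SNP-dense genes under the null;
no analytic correction is applied because the permutation null re-scores
genes the same way, so the bias cancels in the comparison.

## Enrichment score

With the ranked statistics `r_(1) >= ... >= r_(N)` and a pathway S of
`N_H` eligible members (members intersected with the ranked genes), the
running sum walks the list accumulating `+|r_j|^p / N_R` on members
(`N_R = sum_{g in S} |r_g|^p`) and `-1/(N - N_H)` on non-members.  ES is
the maximum of the running sum — the maximum positive deviation, i.e.
enrichment at the top only; depletion is deliberately not tested.  The
weight exponent defaults to `p = 1` (the weighted-statistic convention for
this family of methods) and `p = 0` recovers the classic unweighted KS
statistic, which the tests verify against a direct implementation.  The
leading edge is the set of members at or before the first position where
the sum peaks.

Pathways are tested only when `10 <= N_H <= 200` (bounds configurable); the
filter applies to the *eligible* count, not raw membership.  Degenerate sets
(empty, covering the whole list, or all-zero member statistics) raise an
error on observed data; in a permutation replicate they are recorded as
ES = 0 (neutral) with a loud log message so the null matrix keeps its shape.

## Permutation null, NES, p, FDR

K permutations (default 1000) shuffle case-control labels uniformly within
each stratum, keeping covariates attached to their samples and per-stratum
case counts fixed.  Every replicate re-runs the full chain — association,
meta-analysis, gene scoring, ranking, ES — while the SNP-gene assignment,
the scoreable gene list and the pathway membership stay frozen at their
observed-data values (the assignment depends only on genotypes, so only the
statistics can change; freezing membership keeps the null conditional on
the tested sets).

* Nominal p: `(1 + #{k : ES_k >= ES_obs}) / (K + 1)` — the add-one
  estimator, avoiding p = 0 at finite K.
* NES: `(ES_obs - mean(ES_perm)) / sd(ES_perm)` with the sample (K−1)
  standard deviation; permutation values are standardised by their own
  pathway's mean/sd the same way.  A pathway with zero permutation spread
  gets an undefined NES and is excluded from the FDR with a warning.
* FDR (permutation method, default): for each observed NES* the raw ratio
  is `mean(pooled standardised permutation scores >= NES*) /
  mean(observed NES >= NES*)`, capped at 1.  Each pathway then takes the
  minimum raw ratio over itself and every lower-NES threshold (the usual
  q-value construction), which makes FDR non-increasing in NES.
* `fdr_method="bh"` applies Benjamini-Hochberg to the nominal p-values
  instead, for comparison.  With K = 1 the NES is undefined, so the
  permutation FDR automatically falls back to BH with a warning.

The whole result table is a pure function of the inputs and the seed:
per-permutation seeds are drawn from a child stream of
`EnrichmentParams.seed`.

### Overlap re-analysis

`run_enrichment(..., exclude_genes={"set_name": [genes]})` removes the named
genes from a set before eligibility filtering and re-runs everything —
the standard follow-up when two pathways share genes and one wants to know
whether a signal survives on a pathway's private genes.

## Synthetic studies

The generator emulates the study design this pipeline targets: several
nested case-control strata genotyped on a shared panel, with covariates and
an optional pathway-concentrated genetic signal.  Defaults: four strata
with a roughly 1:3 case:control ratio (179 cases / 521 controls in total),
2,000 independent biallelic SNPs with MAF ~ U(0.05, 0.5) under
Hardy-Weinberg, a 10-chromosome genome of 300 non-overlapping 20-kb genes
separated by 100-kb gaps, and 40 gene sets of 10–50 genes sampled with
overlap allowed.  60% of SNPs fall inside gene bodies and 40% in the gaps,
guaranteeing both mapped and unmapped SNPs so the flank filter is always
exercised.

Disease status follows a population logistic model: case probability
`expit(b0 + log(OR) * burden + c'x)` where the burden sums dosages over one
risk SNP per causal gene (genes drawn from the configured causal pathways),
and `b0` is calibrated to the configured baseline prevalence (default 0.2,
in the range reported for lifetime basal-cell-carcinoma risk in fair-skinned
populations) at mean covariates and mean burden.  Covariates are age
~ N(55 + 2·stratum, 8) — strata differ in covariate means only — and three
standard-normal principal-component scores, with modest default effects
(log-OR 0.02/year of age, 0.15/0.10/0.05 per PC unit).  Strata are filled
to their exact case/control quotas by scanning a per-stratum population
pool (case-control sampling with rejection); the pool is sized at 1.5x the
expected need, capped at 1000x the requested total, and exhausting it
raises an error naming the stratum.  An optional Balding-Nichols drift
parameter adds allele-frequency divergence between strata; it defaults to 0
because the analysis model adjusts for structure through the PCs and the
default tests should be structure-free.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: linkage disequilibrium (SNPs are
independent, so the max-per-gene statistic is better behaved than on real
arrays), genotyping error and missingness, realistic gene-length and
SNP-density heterogeneity, allele-frequency spectra shaped by demography,
and real covariate distributions.  The pipeline's calibration on real
genotypes rests on the permutation null, which conditions on whatever
genotype correlation exists; the simulations verify the machinery, not the
biology.

Randomness is organised as one master seed with fixed-offset child streams
per component (annotation, genotypes, covariates, status draws, pathways,
causal-gene choice), so regenerating any component is reproducible and
independent of the others.

## Numerical and design choices

* Window boundaries inclusive on both ends ("within 20 kb" read as <=);
  boundary behaviour is pinned by tests so results are bit-stable.
* All tie-breaks (representative SNP, gene ranking) are deterministic:
  position, then identifier.
* The achievable floor of the nominal p is 1/(K+1); FDR values of exactly 0
  occur when no pooled permutation score reaches an observed NES.
* Logistic non-identifiability (separation) is detected by non-convergence
  or a diverged coefficient (|beta| > 20) and flagged rather than raised.
* p-values are clipped away from exact 0 so downstream log-scale use is
  safe.
* Gene identity is the annotation's id string; no alias resolution.

## Problem sizes used in the checked results

The deep statistical tests run at desk scale, chosen to keep the suite
fast while leaving the binomial/KS acceptance bands meaningful: null
calibration uses 20 independent studies of 400 cases / 400 controls in two
strata, 2,000 SNPs, 40 pathways and K = 200 score-mode permutations
(~800 pathway p-values); the power check uses 20 studies of 1,000 cases /
1,000 controls with one causal pathway of ten OR-1.5 genes, requiring the
causal pathway to attain the smallest nominal p in at least 80% of
replicates.  Oracle-equivalence checks (enrichment score, meta-analysis,
logistic fits) use hundreds of random small instances at tolerances 1e-12
(closed-form) and 1e-6 (IRLS).  `scripts/acceptance.py` re-runs the
pipeline end-to-end at similar sizes with the exact permutation mode for
the causal-pathway study and score mode for the calibration sweep.

## Known limitations

* No LD-aware gene statistic and no gene-length bias correction beyond what
  the permutation provides.
* No random-effects meta-analysis or heterogeneity statistics; the
  fixed-effect inverse-variance combination assumes a shared effect across
  strata.
* Physical proximity assignment can mis-attribute SNPs regulating distant
  genes; nothing trans-acting is modelled.
* Depletion (negative enrichment) is not tested, by construction of the ES.
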