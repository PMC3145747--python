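"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (pure-Python
loops, closed-form formulas, statsmodels fits) kept separate from the
package's vectorised code paths so they can serve as independent references.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathgwas import SimulationConfig, simulate_study
from pathgwas.mapping import RankedGeneList


# ---------------------------------------------------------------------------
# Independent oracles

def es_bruteforce(stats, member_flags, weight_p):
    """Sequential running-sum enumeration of the weighted KS enrichment score."""
    n = len(stats)
    n_h = sum(bool(m) for m in member_flags)
    assert 0 < n_h < n
    n_r = sum(abs(s) ** weight_p for s, m in zip(stats, member_flags) if m)
    run, best = 0.0, -np.inf
    for s, m in zip(stats, member_flags):
        if m:
            run += abs(s) ** weight_p / n_r
        else:
            run -= 1.0 / (n - n_h)
        best = max(best, run)
    return best


def unweighted_ks_es(member_flags):
    """Classic unweighted KS statistic: hits step 1/N_H, misses 1/(N-N_H)."""
    n = len(member_flags)
    n_h = sum(bool(m) for m in member_flags)
    run, best = 0.0, -np.inf
    for m in member_flags:
        run += 1.0 / n_h if m else -1.0 / (n - n_h)
        best = max(best, run)
    return best


def meta_closed_form(betas, ses):
    w = [1.0 / s**2 for s in ses]
    beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    se = (sum(w)) ** -0.5
    return beta, se


def irls_logistic_oracle(X, y):
    """statsmodels GLM-Binomial fit (IRLS); returns (params, bse)."""
    import statsmodels.api as sm

    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12, maxiter=200)
    return res.params, res.bse


def make_ranked(stats, gene_ids=None) -> RankedGeneList:
    """Build a RankedGeneList from statistics already in descending order."""
    stats = np.asarray(stats, dtype=float)
    assert (np.diff(stats) <= 0).all(), "stats must be non-increasing"
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(len(stats))]
    gene_ids = np.asarray(gene_ids, dtype=object)
    table = pd.DataFrame({"gene_id": gene_ids, "score": stats})
    return RankedGeneList(gene_ids=gene_ids, stats=stats, table=table)


def random_es_instance(rng, n_max=50):
    """Random (ranked stats, membership) pair with 1 <= N_H < N and N_R > 0."""
    n = int(rng.integers(3, n_max + 1))
    stats = np.sort(rng.gamma(1.0, 2.0, size=n))[::-1]
    while True:
        n_h = int(rng.integers(1, n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=n_h, replace=False)] = True
        if stats[flags].sum() > 0:
            return stats, flags


# ---------------------------------------------------------------------------
# Simulated-study fixtures

TINY_CFG = SimulationConfig(
    n_cases_per_stratum=(30, 25),
    n_controls_per_stratum=(70, 60),
    n_snps=300,
    n_genes=60,
    genes_per_chromosome=15,
    n_pathways=8,
    pathway_size_range=(8, 20),
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(TINY_CFG)


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    from pathgwas import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    write_fixture(TINY_CFG, out)
    return out
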