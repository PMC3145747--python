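"""Per-SNP case-control association and cross-stratum meta-analysis.

Within each stratum the additive genetic model is a multivariable logistic
regression of case status on allele dosage plus covariates (intercept, age,
first three principal components by default); the dosage term's Wald estimate
and standard error feed a fixed-effect inverse-variance meta-analysis across
strata:

    w_i = 1 / se_i^2,   beta = sum(w_i b_i) / sum(w_i),   se = sum(w_i)^-1/2,
    z = beta / se,      chi2 = z^2,   p = P(Chi2_1 >= chi2).

The logistic fits are done by a Newton (equivalently iteratively-reweighted
least-squares) solver batched over SNPs: the covariate block of the design is
shared, so per iteration the Hessian blocks for all SNPs are assembled with a
handful of dense matrix products.  A permutation run re-fits hundreds of
thousands of these models, which is why the solver is vectorised rather than
delegated to a generic GLM routine; `statsmodels` serves as the independent
cross-check in the test-suite.

A "score" mode is also provided for permutation nulls: it fits the
covariate-only model once per permutation and computes each SNP's efficient
score statistic (with the matching one-step effect estimate U/V and standard
error V^-1/2), avoiding the per-SNP Newton loop entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import PipelineError
from .io import DEFAULT_COVARIATES, MISSING_DOSAGE, GenotypeMatrix

logger = logging.getLogger(__name__)

_TOL = 1e-8
_MAX_ITER = 50
_ETA_CLIP = 30.0
_BETA_DIVERGED = 20.0

FLAG_OK = "ok"
FLAG_MONOMORPHIC = "monomorphic"
FLAG_UNSTABLE = "unstable"
FLAG_TOO_FEW = "too_few_cases_or_controls"


@dataclass
class SnpFit:
    """Dosage-term estimate from a single-stratum logistic fit."""

    beta: float
    se: float
    flag: str

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


# ---------------------------------------------------------------------------
# Newton / IRLS solvers

def _newton_logistic(X: np.ndarray, y: np.ndarray,
                     tol: float = _TOL, max_iter: int = _MAX_ITER):
    """Plain Newton fit of a logistic model; returns (beta, converged)."""
    n, d = X.shape
    beta = np.zeros(d)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        g = X.T @ (y - mu)
        delta = np.linalg.solve(H, g)
        beta += delta
        if np.abs(delta).max() < tol:
            converged = True
            break
    return beta, converged


def _newton_logistic_batch(
    G: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    warm: np.ndarray | None = None,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
):
    """Batched Newton fit of status ~ dosage + covariates for S SNPs at once.

    Parameters
    ----------
    G : (S, n) float array of dosages (masked entries may hold anything).
    Z : (n, c) shared covariate design including the intercept column.
    y : (n,) 0/1 outcomes.
    mask : optional (S, n) 0/1 array; 0 drops a sample from that SNP's fit.
    warm : optional (c,) warm-start for the covariate coefficients.

    Returns
    -------
    beta : (S,) dosage log-odds estimates.
    se : (S,) Wald standard errors.
    converged : (S,) bool.
    """
    S, n = G.shape
    c = Z.shape[1]
    Gm = G if mask is None else G * mask
    ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(n, c * c)
    beta_g = np.zeros(S)
    gamma = np.tile(np.zeros(c) if warm is None else warm, (S, 1))
    delta_max = np.full(S, np.inf)
    H = np.empty((S, c + 1, c + 1))
    for _ in range(max_iter):
        eta = np.clip(Gm * beta_g[:, None] + gamma @ Z.T, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[None, :] - mu
        if mask is not None:
            w *= mask
            r *= mask
        wG = w * Gm
        H[:, 0, 0] = np.einsum("sn,sn->s", wG, Gm) + 1e-12
        B = wG @ Z
        H[:, 0, 1:] = B
        H[:, 1:, 0] = B
        H[:, 1:, 1:] = (w @ ZZ).reshape(S, c, c)
        H[:, 1:, 1:][:, np.arange(c), np.arange(c)] += 1e-12
        U = np.empty((S, c + 1))
        U[:, 0] = np.einsum("sn,sn->s", Gm, r)
        U[:, 1:] = r @ Z
        delta = np.linalg.solve(H, U[:, :, None])[:, :, 0]
        beta_g += delta[:, 0]
        gamma += delta[:, 1:]
        delta_max = np.abs(delta).max(axis=1)
        if delta_max.max() < tol:
            break
    converged = (delta_max < tol) & (np.abs(beta_g) < _BETA_DIVERGED)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov00 = np.linalg.inv(H)[:, 0, 0]
        se = np.sqrt(cov00)
    bad = ~np.isfinite(se) | (se <= 0)
    converged &= ~bad
    return beta_g, se, converged


def _score_stats(G: np.ndarray, Z: np.ndarray, y: np.ndarray):
    """Efficient-score statistics for all SNPs under the covariate-only null.

    Returns one-step estimates ``beta = U/V`` and ``se = V^-1/2`` so the
    downstream meta-analysis sees the same interface as the Wald path.
    Requires complete dosages (the simulator emits none missing); callers with
    missing data must impute or use the exact mode.
    """
    gamma, conv = _newton_logistic(Z, y)
    mu = expit(np.clip(Z @ gamma, -_ETA_CLIP, _ETA_CLIP))
    w = mu * (1 - mu)
    r = y - mu
    U = G @ r
    WZ = Z * w[:, None]
    A = Z.T @ WZ
    B = G @ WZ
    BAinv = np.linalg.solve(A, B.T).T
    V = (G * G) @ w - np.einsum("sc,sc->s", BAinv, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(V > 1e-12, U / np.maximum(V, 1e-300), np.nan)
        se = np.where(V > 1e-12, 1.0 / np.sqrt(np.maximum(V, 1e-300)), np.nan)
    ok = conv & (V > 1e-12) & np.isfinite(se)
    return beta, se, ok


# ---------------------------------------------------------------------------
# Public single-SNP fit

def _design(pheno: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> np.ndarray:
    cols = [np.ones(len(pheno))]
    cols += [pheno[c].to_numpy(dtype=float) for c in covariates]
    return np.column_stack(cols)


def fit_snp_logistic(
    dosage: np.ndarray,
    pheno: pd.DataFrame,
    stratum: str,
    covariates=DEFAULT_COVARIATES,
) -> SnpFit:
    """Additive-dosage logistic fit of status on (dosage, covariates) in one stratum.

    Missing dosages (negative values or NaN) are dropped for this SNP.
    Degenerate inputs return a flagged :class:`SnpFit` rather than raising:
    ``monomorphic`` for constant dosage, ``unstable`` for separation or
    non-convergence, ``too_few_cases_or_controls`` below 2 of either.
    """
    sel = pheno["stratum"].to_numpy() == stratum
    if not sel.any():
        raise PipelineError(f"no samples in stratum {stratum}")
    dosage = np.asarray(dosage, dtype=float)[sel]
    sub = pheno.loc[sel]
    keep = np.isfinite(dosage) & (dosage >= 0)
    dosage, sub = dosage[keep], sub.loc[keep]
    y = sub["status"].to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        return SnpFit(np.nan, np.nan, FLAG_TOO_FEW)
    if np.unique(dosage).size < 2:
        return SnpFit(np.nan, np.nan, FLAG_MONOMORPHIC)
    Z = _design(sub, covariates)
    beta, se, conv = _newton_logistic_batch(dosage[None, :], Z, y)
    if not conv[0]:
        return SnpFit(float(beta[0]), float(se[0]), FLAG_UNSTABLE)
    return SnpFit(float(beta[0]), float(se[0]), FLAG_OK)


# ---------------------------------------------------------------------------
# Meta-analysis

def meta_analyze(per_stratum):
    """Fixed-effect inverse-variance combination of (beta, se) pairs.

    Accepts an iterable of ``(beta_i, se_i)``; entries with non-finite beta or
    non-positive se are skipped.  Returns ``(beta, se, z, chi2, p)`` or raises
    :class:`PipelineError` when nothing is combinable.
    """
    betas, ses = [], []
    for b, s in per_stratum:
        if np.isfinite(b) and np.isfinite(s) and s > 0:
            betas.append(float(b))
            ses.append(float(s))
    if not betas:
        raise PipelineError("meta_analyze: no stratum with a finite estimate")
    w = 1.0 / np.square(ses)
    beta = float(np.sum(w * np.asarray(betas)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, df=1))
    return beta, se, z, chi2, max(p, np.nextafter(0, 1))


def _meta_vectorized(betas: np.ndarray, ses: np.ndarray):
    """Row-wise inverse-variance meta over an (S, n_strata) grid with NaN gaps."""
    usable = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    w = np.where(usable, 1.0 / np.where(usable, ses, 1.0) ** 2, 0.0)
    wsum = w.sum(axis=1)
    n_used = usable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(wsum > 0, (w * np.where(usable, betas, 0.0)).sum(axis=1) / wsum, np.nan)
        se = np.where(wsum > 0, 1.0 / np.sqrt(wsum), np.nan)
        z = beta / se
    chi2 = z * z
    p = stats.chi2.sf(chi2, df=1)
    return beta, se, z, chi2, p, n_used


# ---------------------------------------------------------------------------
# Whole-cohort GWAS

class StratumData:
    """Pre-extracted per-stratum arrays, reusable across permutations."""

    def __init__(self, label: str, G: np.ndarray, Z: np.ndarray, y: np.ndarray,
                 mask: np.ndarray | None, mono: np.ndarray):
        self.label = label
        self.G = G          # (S, n) float64, missing zeroed
        self.Z = Z          # (n, c)
        self.y = y          # (n,)
        self.mask = mask    # (S, n) or None
        self.mono = mono    # (S,) bool: monomorphic / unusable in this stratum


def prepare_strata(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> list[StratumData]:
    """Align samples, build per-stratum designs, flag monomorphic SNPs."""
    geno_index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing = [s for s in pheno["sample_id"] if s not in geno_index]
    if missing:
        raise PipelineError(f"phenotype samples missing from genotypes: {missing[:5]}")
    strata = []
    for label in sorted(pheno["stratum"].unique()):
        sub = pheno.loc[pheno["stratum"] == label]
        rows = np.array([geno_index[s] for s in sub["sample_id"]], dtype=np.intp)
        D = genotypes.dosages[rows].T.astype(np.float64)  # (S, n)
        miss = D == MISSING_DOSAGE
        mask = None
        if miss.any():
            mask = (~miss).astype(np.float64)
            D = np.where(miss, 0.0, D)
        y = sub["status"].to_numpy(dtype=float)
        Z = _design(sub, covariates)
        # constant dosage among non-missing samples -> monomorphic here
        if mask is None:
            mono = np.ptp(D, axis=1) == 0
        else:
            mx = np.where(mask > 0, D, -np.inf).max(axis=1)
            mn = np.where(mask > 0, D, np.inf).min(axis=1)
            mono = ~(mx > mn)  # constant among non-missing, or none left
            mono |= mask.sum(axis=1) < 4
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            mono = np.ones_like(mono)
        strata.append(StratumData(label, np.ascontiguousarray(D), Z, y, mask, mono))
    return strata


def _stratum_fit(data: StratumData, y: np.ndarray, mode: str):
    """Fit every usable SNP in one stratum; returns (beta, se) with NaN gaps."""
    S = data.G.shape[0]
    beta = np.full(S, np.nan)
    se = np.full(S, np.nan)
    usable = ~data.mono
    if (y == 1).sum() < 2 or (y == 0).sum() < 2 or not usable.any():
        return beta, se
    if mode == "score":
        if data.mask is not None:
            raise PipelineError("score mode requires complete dosages")
        b, s, ok = _score_stats(data.G[usable], data.Z, y)
    else:
        warm, _ = _newton_logistic(data.Z, y)
        b, s, ok = _newton_logistic_batch(
            data.G[usable], data.Z, y,
            mask=None if data.mask is None else data.mask[usable],
            warm=warm,
        )
    b = np.where(ok, b, np.nan)
    s = np.where(ok, s, np.nan)
    beta[usable] = b
    se[usable] = s
    return beta, se


@dataclass
class GwasResult:
    """Meta-analysed per-SNP associations plus the per-stratum estimates."""

    meta: pd.DataFrame                       # snp_id chrom pos beta se z chi2 p n_strata_used
    per_stratum: dict[str, pd.DataFrame]     # label -> (snp_id, beta, se)
    excluded_snps: list[str]


def run_gwas(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    mode: str = "wald",
    strata: list[StratumData] | None = None,
    y_override: dict[str, np.ndarray] | None = None,
) -> GwasResult:
    """Fit every SNP in every stratum and meta-analyse across strata.

    ``mode`` selects the per-stratum statistic: ``"wald"`` (full logistic fit,
    the default and reference) or ``"score"`` (efficient score at the
    covariate-only fit; used by fast permutation nulls).  SNPs unusable in
    every stratum are excluded from the output and logged.  ``strata`` and
    ``y_override`` let permutation loops reuse the prepared designs.
    """
    if mode not in ("wald", "score"):
        raise PipelineError(f"unknown association mode {mode!r}")
    if strata is None:
        strata = prepare_strata(genotypes, pheno, covariates)
    S = genotypes.n_snps
    nk = len(strata)
    betas = np.full((S, nk), np.nan)
    ses = np.full((S, nk), np.nan)
    for k, data in enumerate(strata):
        y = data.y if y_override is None else y_override[data.label]
        betas[:, k], ses[:, k] = _stratum_fit(data, y, mode)
    beta, se, z, chi2, p, n_used = _meta_vectorized(betas, ses)
    keep = n_used > 0
    excluded = [str(s) for s in genotypes.snp_ids[~keep]]
    if excluded:
        logger.warning(
            "run_gwas: excluded %d SNP(s) unusable in every stratum (first: %s)",
            len(excluded), excluded[:3],
        )
    if not keep.any():
        raise PipelineError("run_gwas: no usable SNPs")
    meta = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids[keep],
            "chrom": genotypes.chrom[keep],
            "pos": genotypes.pos[keep],
            "beta": beta[keep],
            "se": se[keep],
            "z": z[keep],
            "chi2": chi2[keep],
            "p": np.clip(p[keep], np.nextafter(0, 1), 1.0),
            "n_strata_used": n_used[keep],
        }
    )
    per_stratum = {
        data.label: pd.DataFrame(
            {"snp_id": genotypes.snp_ids, "beta": betas[:, k], "se": ses[:, k]}
        )
        for k, data in enumerate(strata)
    }
    return GwasResult(meta=meta, per_stratum=per_stratum, excluded_snps=excluded)


# ---------------------------------------------------------------------------
# Phenotype permutation

def permute_phenotypes(pheno: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle case-control labels uniformly at random within each stratum.

    Covariates stay attached to their samples, so per-stratum case counts and
    covariate-outcome confounding structure under the null are preserved.
    """
    rng = np.random.default_rng(seed)
    out = pheno.copy()
    status = out["status"].to_numpy().copy()
    strata = out["stratum"].to_numpy()
    for label in sorted(pd.unique(strata)):
        rows = np.flatnonzero(strata == label)
        status[rows] = status[rows[rng.permutation(rows.size)]]
    out["status"] = status
    return out


def permuted_status_by_stratum(
    strata: list[StratumData], seed: int
) -> dict[str, np.ndarray]:
    """Within-stratum label shuffles on prepared designs (permutation fast path)."""
    rng = np.random.default_rng(seed)
    out = {}
    for data in sorted(strata, key=lambda d: d.label):
        out[data.label] = data.y[rng.permutation(data.y.size)]
    return out
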