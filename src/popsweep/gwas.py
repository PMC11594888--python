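"""Mixed-linear-model association with a kinship-structured polygenic term.

Model: y = C alpha + g beta + u + e with u ~ (0, sg^2 K), e ~ (0, se^2 I).
K is eigendecomposed once; the REML likelihood is profiled over
lambda = sg^2/se^2 on a log grid with bounded local refinement.  By default
lambda is estimated once under the covariates-only null and reused for every
SNP (the standard approximation at this scale); exact per-SNP optimization
is available behind a flag.  Wald p-values use the F(1, n-p) reference, so
with K = I results reduce exactly to per-SNP OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_GRID_POINTS = 81

#: median of the chi-square(1) distribution, for genomic control
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("kinship matrix is not symmetric")


@dataclass
class GwasResult:
    table: "pd.DataFrame"  # chrom, pos, beta, se, wald, p
    threshold: float
    lambda_gc: float
    lambda_reml: float


def imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Samples x variants dosage matrix with missing calls imputed to the
    per-variant mean."""
    calls = g.calls.astype(float)
    present = g.calls != MISSING
    n_called = present.sum(axis=0)
    if np.any(n_called == 0):
        raise ValueError("variant with no called genotypes")
    mean = np.where(present, calls, 0.0).sum(axis=0) / n_called
    return np.where(present, calls, mean[None, :])


def kinship_centered(g: GenotypeMatrix) -> KinshipMatrix:
    """Centered relatedness matrix K = W W^T / p with mean-centered dosage
    columns (p = number of variants)."""
    if g.n_variants == 0:
        raise ValueError("no variants for kinship computation")
    W = imputed_dosage(g)
    W = W - W.mean(axis=0, keepdims=True)
    K = (W @ W.T) / g.n_variants
    return KinshipMatrix(sample_ids=list(g.samples), values=K)


def _reml_neg_loglik(
    log10_lam: float, s: np.ndarray, Uy: np.ndarray, UX: np.ndarray
) -> float:
    """Negative REML log-likelihood at lambda, in the eigenbasis of K."""
    lam = 10.0**log10_lam
    w = 1.0 / (lam * s + 1.0)
    n, p = UX.shape
    XtWX = UX.T @ (w[:, None] * UX)
    XtWy = UX.T @ (w * Uy)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = Uy - UX @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return np.inf
    df = n - p
    sigma2 = rss / df
    _, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(UX.T @ UX)
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * sigma2)
        + df
        + np.sum(np.log(lam * s + 1.0))
        + logdet_XtWX
        - logdet_XtX
    )
    return -ll


def estimate_lambda(
    s: np.ndarray, Uy: np.ndarray, UX: np.ndarray
) -> tuple[float, float]:
    """REML estimate of lambda = sg^2/se^2 by grid search plus bounded
    refinement.  Returns (lambda, REML log-likelihood at the optimum)."""
    grid = np.linspace(*_LOG10_LAMBDA_RANGE, _GRID_POINTS)
    vals = np.array([_reml_neg_loglik(x, s, Uy, UX) for x in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, Uy, UX), method="bounded"
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    fun = min(float(res.fun), float(vals[i]))
    return 10.0**best, -fun


def mlm_associate(
    y: np.ndarray,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    per_snp_reml: bool = False,
) -> GwasResult:
    """Per-SNP mixed-model Wald test of the additive dosage effect on y.

    ``covariates`` (n x c, without intercept) are optional fixed effects; an
    intercept is always included.  Monomorphic SNPs are skipped with NaN
    results.
    """
    import pandas as pd

    y = np.asarray(y, dtype=float)
    n = g.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype vector not aligned to samples")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    K.validate()
    if K.sample_ids != g.samples:
        raise ValueError("kinship sample order does not match genotypes")

    C = np.ones((n, 1))
    if covariates is not None:
        C = np.hstack([C, np.asarray(covariates, dtype=float)])
    p_cov = C.shape[1]

    s, U = np.linalg.eigh(K.values)
    s = np.clip(s, 0.0, None)
    Uy = U.T @ y
    UC = U.T @ C

    lam, ll_opt = estimate_lambda(s, Uy, UC)
    logger.info("null-model REML lambda = %.4g", lam)

    G = imputed_dosage(g)
    UG = U.T @ G

    mono = np.ptp(G, axis=0) == 0
    df = n - p_cov - 1

    if per_snp_reml:
        beta, se = np.full(g.n_variants, np.nan), np.full(g.n_variants, np.nan)
        for j in range(g.n_variants):
            if mono[j]:
                continue
            UXj = np.hstack([UC, UG[:, j : j + 1]])
            lam_j, _ = estimate_lambda(s, Uy, UXj)
            b, e_ = _gls_last_column(lam_j, s, Uy, UC, UG[:, j : j + 1])
            beta[j], se[j] = b[0], e_[0]
    else:
        beta, se = _gls_last_column(lam, s, Uy, UC, UG)
        beta[mono] = np.nan
        se[mono] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    pvals = stats.f.sf(wald, 1, df)

    n_tests = int(np.sum(~mono))
    threshold = bonferroni_threshold(alpha, n_tests) if n_tests else np.nan
    lam_gc, _ = qq_lambda(pvals[~np.isnan(pvals)])
    table = pd.DataFrame(
        dict(
            chrom=g.variants["chrom"],
            pos=g.variants["pos"],
            beta=beta,
            se=se,
            wald=wald,
            p=pvals,
        )
    )
    return GwasResult(table=table, threshold=threshold, lambda_gc=lam_gc, lambda_reml=lam)


def _gls_last_column(
    lam: float,
    s: np.ndarray,
    Uy: np.ndarray,
    UC: np.ndarray,
    UG: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized GLS of y on [C, g_j] for every column g_j, returning the
    estimate and standard error of the g coefficient (partitioned inverse)."""
    n, p = UC.shape
    m = UG.shape[1]
    w = 1.0 / (lam * s + 1.0)
    Wc = w[:, None] * UC
    CtWC = UC.T @ Wc
    CtWy = Wc.T @ Uy
    CtWC_inv = np.linalg.inv(CtWC)
    ytWy = float(np.sum(w * Uy**2))

    CtWg = Wc.T @ UG  # p x m
    gtWg = np.einsum("ij,ij->j", UG, w[:, None] * UG)  # m
    gtWy = UG.T @ (w * Uy)  # m

    A = CtWC_inv @ CtWg  # p x m
    schur = gtWg - np.einsum("ij,ij->j", CtWg, A)  # m
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_g = (gtWy - A.T @ CtWy) / schur

    # residual sum of squares of the full model, per SNP
    beta_c = CtWC_inv @ (CtWy[:, None] - CtWg * beta_g[None, :])  # p x m
    rss = (
        ytWy
        - np.einsum("i,ij->j", CtWy, beta_c)
        - gtWy * beta_g
    )
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.clip(rss, 0.0, None) / df
        se_g = np.sqrt(sigma2 / schur)
    bad = schur <= 0
    beta_g = np.where(bad, np.nan, beta_g)
    se_g = np.where(bad, np.nan, se_g)
    return beta_g, se_g


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def qq_lambda(pvalues: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control lambda and the observed/expected quantile table.

    lambda = median observed chi-square(1) statistic / chi-square(1) median.
    The table has columns (expected -log10 p, observed -log10 p).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no valid p-values")
    chi2_obs = stats.chi2.ppf(1.0 - p, df=1)
    lam = float(np.median(chi2_obs) / CHI2_1_MEDIAN)
    obs = np.sort(p)
    exp = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    with np.errstate(divide="ignore"):
        table = np.column_stack([-np.log10(exp), -np.log10(obs)])
    return lam, table
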