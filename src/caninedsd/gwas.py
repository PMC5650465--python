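"""Logistic mixed-model association with a genetic relationship matrix.

The null model is a logistic mixed model

    logit P(y_i = 1) = x_i' beta + u_i,   u ~ N(0, tau * K)

with the centered genetic relationship matrix (GRM) K as random-effect
covariance and genotype principal components as fixed effects, fitted by
penalized quasi-likelihood (PQL): iterate the logistic working response and
weights, solve the linear mixed-model equations, and update the variance
component tau by an average-information step with a fixed-point fallback.
Each variant is then tested with the score statistic U^2 / V, U = g'(y -
mu_hat), V = g' P g, which costs one matrix product per scan rather than one
model fit per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix


@dataclass
class KinshipMatrix:
    """Realized-relatedness matrix with its sample order."""

    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape inconsistent with sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")


def centered_grm(matrix: GenotypeMatrix, mean_impute: bool = False) -> KinshipMatrix:
    """Centered GRM: K = Z Z' / p with Z the column-mean-centered dosages.

    Requires complete data unless ``mean_impute`` is set (missing dosages
    replaced by the site mean, which contributes zero after centering).
    """
    if matrix.n_sites == 0:
        raise ValueError("cannot build a GRM from zero sites")
    has_missing = (matrix.calls == MISSING).any()
    if has_missing and not mean_impute:
        raise ValueError("missing calls present; prefilter or set mean_impute=True")
    d = matrix.dosage(mean_impute=has_missing)
    z = d - d.mean(axis=0, keepdims=True)
    k = z @ z.T / matrix.n_sites
    return KinshipMatrix(k, list(matrix.samples))


def genotype_pca(
    matrix: GenotypeMatrix,
    maf_min: float = 0.01,
    thin_every: int = 100,
    k: int = 5,
    scale: bool = False,
) -> np.ndarray:
    """Top-k principal component scores of the filtered dosage matrix.

    Sites with MAF below ``maf_min`` are removed and every
    ``thin_every``-th survivor kept; dosages are mean-imputed and centered
    (optionally scaled by sqrt(2 p (1-p))).  Sign convention: the
    largest-magnitude loading of each component is positive.  If the matrix
    has rank below ``k``, fewer components are returned with a warning.
    """
    import warnings

    if matrix.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    d = matrix.dosage(mean_impute=True)
    af = d.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = np.nonzero(maf >= maf_min)[0]
    if thin_every > 1:
        keep = keep[::thin_every]
    d = d[:, keep]
    if d.shape[1] == 0:
        raise ValueError("no sites survive the PCA prefilter")
    z = d - d.mean(axis=0, keepdims=True)
    if scale:
        p = d.mean(axis=0) / 2.0
        sd = np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
        z = z / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    if rank < k:
        warnings.warn(f"genotype matrix rank {rank} < requested {k} components")
    k_eff = min(k, rank)
    scores = u[:, :k_eff] * s[:k_eff]
    for j in range(k_eff):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


@dataclass
class NullModelFit:
    """Fitted PQL null model; inputs retained for the score-test scan."""

    beta: np.ndarray
    tau: float
    mu: np.ndarray
    weights: np.ndarray
    P: np.ndarray  # projection on the working-response covariance
    X: np.ndarray
    y: np.ndarray
    converged: bool
    n_iter: int
    trajectory: list[float] = field(default_factory=list)


def fit_null_glmm(
    y: Sequence[float],
    covariates: np.ndarray | None,
    kinship: KinshipMatrix | np.ndarray,
    tau0: float = 0.0,
    fix_tau: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
    ridge: float = 1e-8,
    tau_max: float = 25.0,
) -> NullModelFit:
    """PQL fit of the logistic mixed null model.

    ``covariates`` excludes the intercept, which is always added.  Each
    outer iteration refreshes the logistic working response and weights,
    then profiles the variance component: tau is set to the restricted
    maximum likelihood of the working linear mixed model by bounded 1-D
    optimisation on [0, tau_max] (single-step AI updates oscillate on
    strongly confounded small pedigrees, so the profiled update is used
    throughout).  On separation the working weights collapse; a small
    ridge keeps coefficients bounded and the fit reports
    ``converged=False`` rather than raising.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    n = y.size
    K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
    X = np.column_stack([np.ones(n)] + ([np.asarray(covariates, float).reshape(n, -1)] if covariates is not None else []))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates (with intercept) are rank deficient")

    # plain IRLS start for beta
    beta = _irls_logistic(y, X, ridge)
    tau = float(tau0)
    eta = X @ beta
    converged = False
    trajectory = []
    it = 0
    eye = np.eye(n)
    for it in range(1, max_iter + 1):
        mu = _expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        winv = 1.0 / w
        if not fix_tau:
            res = minimize_scalar(
                _reml_neg_loglik,
                bounds=(0.0, tau_max),
                method="bounded",
                args=(K, winv, X, z, ridge),
                options={"xatol": min(tol, 1e-6)},
            )
            tau_new = max(float(res.x), 0.0)
            if tau_new < 1e-8 and _reml_neg_loglik(0.0, K, winv, X, z, ridge) <= res.fun:
                tau_new = 0.0
        else:
            tau_new = tau
        sigma_inv = np.linalg.inv(tau_new * K + np.diag(winv) + ridge * eye)
        xtsx = X.T @ sigma_inv @ X
        beta_new = np.linalg.solve(xtsx + ridge * np.eye(X.shape[1]), X.T @ sigma_inv @ z)
        u = tau_new * (K @ (sigma_inv @ (z - X @ beta_new)))
        eta_new = X @ beta_new + u
        delta = max(
            float(np.max(np.abs(beta_new - beta)) / (1 + np.max(np.abs(beta)))),
            abs(tau_new - tau) / (1 + abs(tau)),
        )
        beta, tau, eta = beta_new, tau_new, eta_new
        trajectory.append(tau)
        if delta < tol:
            converged = True
            break

    mu = _expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    sigma = tau * K + np.diag(1.0 / w)
    sigma_inv = np.linalg.inv(sigma + ridge * np.eye(n))
    xtsx = X.T @ sigma_inv @ X
    P = sigma_inv - sigma_inv @ X @ np.linalg.solve(xtsx + ridge * np.eye(X.shape[1]), X.T @ sigma_inv)
    return NullModelFit(beta, tau, mu, w, P, X, y, converged, it, trajectory)


def _reml_neg_loglik(
    tau: float,
    K: np.ndarray,
    winv: np.ndarray,
    X: np.ndarray,
    z: np.ndarray,
    ridge: float,
) -> float:
    """Negative restricted log-likelihood of the working LMM at tau."""
    from scipy.linalg import cho_factor, cho_solve

    n = z.size
    sigma = tau * K + np.diag(winv) + ridge * np.eye(n)
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.log(np.diag(c)).sum())
    sinv_z = cho_solve((c, low), z)
    sinv_X = cho_solve((c, low), X)
    xtsx = X.T @ sinv_X
    sign, logdet_x = np.linalg.slogdet(xtsx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtsx, X.T @ sinv_z)
    zPz = float(z @ sinv_z - (X.T @ sinv_z) @ beta)
    return 0.5 * (logdet + logdet_x + zPz)


def _expit(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _irls_logistic(y: np.ndarray, X: np.ndarray, ridge: float = 1e-8, n_iter: int = 50) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        mu = _expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = X @ beta + (y - mu) / w
        xtwx = (X * w[:, None]).T @ X
        beta_new = np.linalg.solve(xtwx + ridge * np.eye(X.shape[1]), (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def score_test_scan(fit: NullModelFit, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site score test against the fitted null model.

    Monomorphic sites get p = 1 and a flag.  Sites with missing calls are
    tested on the genotyped subset (carriers of a missing call are skipped
    for that site, using the corresponding sub-block of the projection).
    Returns a DataFrame with chrom, pos, statistic, p, neg_log10_p, flag.
    """
    resid = fit.y - fit.mu
    d = fit.matrix_dosage if hasattr(fit, "matrix_dosage") else matrix.dosage()
    n, p_sites = d.shape
    stat = np.full(p_sites, np.nan)
    pval = np.ones(p_sites)
    flags = np.array([""] * p_sites, dtype=object)

    complete = ~np.isnan(d).any(axis=0)
    mono = np.array([len(np.unique(d[:, j][~np.isnan(d[:, j])])) <= 1 for j in range(p_sites)])

    g = d[:, complete & ~mono]
    if g.shape[1]:
        U = g.T @ resid
        PG = fit.P @ g
        V = np.einsum("ij,ij->j", g, PG)
        V = np.maximum(V, 1e-300)
        s = U**2 / V
        stat[complete & ~mono] = s
        pval[complete & ~mono] = stats.chi2.sf(s, 1)

    for j in np.nonzero(~complete & ~mono)[0]:
        gj = d[:, j]
        obs = ~np.isnan(gj)
        go = gj[obs]
        if len(np.unique(go)) <= 1:
            mono[j] = True
            continue
        U = go @ resid[obs]
        V = go @ (fit.P[np.ix_(obs, obs)] @ go)
        if V <= 0:
            flags[j] = "nonpositive_variance"
            continue
        stat[j] = U**2 / V
        pval[j] = stats.chi2.sf(stat[j], 1)
        flags[j] = "missing_skipped"

    flags[mono] = "monomorphic"
    pval[mono] = 1.0
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "statistic": stat,
            "p": pval,
            "neg_log10_p": -np.log10(np.clip(pval, np.finfo(float).tiny, None)),
            "flag": flags,
        }
    )


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor lambda: median chi2 / its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, 1))


def write_scan_tsv(scan: pd.DataFrame, path: str | Path, bh: np.ndarray | None = None) -> None:
    """Manhattan-plot-ready TSV: chrom, pos, statistic, p, BH-adjusted p."""
    out = scan.copy()
    if bh is not None:
        out["p_bh"] = bh
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
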