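"""Latent-factor and PCA-based genome scans with shared calibration machinery.

Two scans complement the RDA ordination:

* :class:`LFMMRidge` — a ridge-penalized latent factor mixed model.  Genotype
  dosages are decomposed into environmental effects plus ``K`` latent factors
  absorbing population structure; per-locus association z-scores are then
  computed per environmental variable conditioning on the estimated factors,
  recalibrated by the genomic inflation factor (GIF) and converted to
  chi-square(1) p-values with FDR control.

* :class:`PCAdaptScan` — an outlier scan flagging loci excessively related to
  population structure: loci are regressed on the ``K`` leading principal
  components, the resulting z-score vectors are summarized by a robust
  Mahalanobis distance, GIF-rescaled, and referred to chi-square(K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScanConfig",
    "ScanResult",
    "LFMMRidge",
    "PCAdaptScan",
    "lfmm_ridge_fit",
    "lfmm_scan",
    "pcadapt_scan",
    "genomic_inflation_factor",
    "fdr_adjust",
]


@dataclass(frozen=True)
class ScanConfig:
    """Shared scan settings.

    ``k`` is the number of latent factors / principal components (chosen from
    prior knowledge of the population structure, e.g. the number of genetic
    clusters); ``q_threshold`` is the FDR level for calling outliers.
    """

    k: int = 3
    ridge_lambda: float = 1e-5
    q_threshold: float = 0.01
    max_iter: int = 100
    tol: float = 1e-6
    fdr_method: str = "benjamini_hochberg"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.ridge_lambda <= 0:
            raise ValueError("ridge_lambda must be > 0")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")


@dataclass
class ScanResult:
    """Per-locus scan output.

    ``table`` is long format (locus_id, variable, stat, stat_calibrated, p,
    q, selected); single-statistic scans use variable = None.  ``selected``
    holds the method-level candidate locus ids (union over variables);
    ``selected_by_variable`` the per-variable lists; ``gif`` the genomic
    inflation factor(s) applied.
    """

    method: str
    table: pd.DataFrame
    selected: list[str]
    selected_by_variable: dict[str, list[str]] = field(default_factory=dict)
    gif: dict[str, float] | float = 1.0
    k: int = 0
    converged: bool = True


def genomic_inflation_factor(statistics, df: int) -> float:
    """GIF = median(observed chi-square stats) / median of chi-square(df)."""
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size == 0:
        raise ValueError("empty statistics")
    if (statistics < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(statistics) / stats.chi2.ppf(0.5, df))


def _storey_pi0(p: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid and
    smoothed with a cubic polynomial evaluated at the largest lambda.
    """
    lam = np.arange(0.05, 0.95, 0.05)
    pi0 = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    coef = np.polyfit(lam, pi0, 3)
    return float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0)) or 1.0


def fdr_adjust(p_values, method: str = "benjamini_hochberg") -> np.ndarray:
    """FDR-adjusted q-values (Benjamini-Hochberg, or Storey's pi0-weighted)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "benjamini_hochberg":
        return q_bh
    if method == "storey":
        return np.minimum(_storey_pi0(p) * q_bh, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Xc / sd


def _truncated_svd(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-k factorization M ~ U V^T (U n x k, V m x k)."""
    if k == 0:
        return np.zeros((M.shape[0], 0)), np.zeros((M.shape[1], 0))
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    return u[:, :k] * s[:k], vt[:k].T


class LFMMRidge(BaseEstimator):
    """Ridge latent factor mixed model.

    Minimizes ``||Y - X B^T - U V^T||^2 + lambda ||B||^2`` by block
    coordinate descent: (U, V) from the rank-K truncated SVD of the
    environmental residual, B from the ridge normal equations given the
    factor residual.  The objective is non-increasing at every step.
    """

    def __init__(self, k: int = 3, ridge_lambda: float = 1e-5,
                 max_iter: int = 100, tol: float = 1e-6):
        self.k = k
        self.ridge_lambda = ridge_lambda
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        Xa = np.asarray(X, dtype=float)
        Ya = np.asarray(Y, dtype=float)
        if np.isnan(Ya).any():
            raise ValueError("Y must be complete (impute first)")
        n, L = Ya.shape
        if self.k >= min(n, L):
            raise ValueError(f"k={self.k} must be < min(n, loci) = {min(n, L)}")
        Yc = Ya - Ya.mean(axis=0)
        Xs = _standardize(Xa)
        q = Xs.shape[1]

        XtX = Xs.T @ Xs + self.ridge_lambda * np.eye(q)
        solve = np.linalg.inv(XtX) @ Xs.T
        B = np.zeros((L, q))
        U = np.zeros((n, self.k))
        V = np.zeros((L, self.k))
        objective = [float((Yc**2).sum())]
        self.converged_ = False
        for _ in range(self.max_iter):
            U, V = _truncated_svd(Yc - Xs @ B.T, self.k)
            B = (solve @ (Yc - U @ V.T)).T
            resid = Yc - Xs @ B.T - U @ V.T
            obj = float((resid**2).sum() + self.ridge_lambda * (B**2).sum())
            objective.append(obj)
            if abs(objective[-2] - obj) <= self.tol * max(1.0, objective[-2]):
                self.converged_ = True
                break
        if not self.converged_:
            warnings.warn("LFMM ridge did not converge; returning last iterate")
        self.B_ = B
        self.U_ = U
        self.V_ = V
        self.objective_path_ = np.asarray(objective)
        self._Yc = Yc
        self._Xs = Xs
        return self


def lfmm_ridge_fit(Y, X, config: ScanConfig) -> LFMMRidge:
    """Fit the ridge LFMM; returns the estimator with ``B_``, ``U_``, ``V_``."""
    return LFMMRidge(
        k=config.k, ridge_lambda=config.ridge_lambda,
        max_iter=config.max_iter, tol=config.tol,
    ).fit(X, Y)


def _batched_ols_z(D: np.ndarray, Yc: np.ndarray, col: int) -> np.ndarray:
    """z-statistics of D's column ``col`` from per-locus OLS refits of Yc on D."""
    n, p = D.shape
    if n <= p:
        raise ValueError("need more rows than refit covariates")
    G = np.linalg.inv(D.T @ D)
    coef = G @ (D.T @ Yc)  # p x L
    resid = Yc - D @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * G[col, col], 1e-300))
    return coef[col] / se


def lfmm_scan(Y, X, config: ScanConfig, locus_ids=None) -> ScanResult:
    """LFMM association scan: one test per locus per environmental variable.

    Latent factors are estimated once from the full model; each variable is
    then tested per locus by refitting the locus on [variable, U] — the
    factors absorb population structure while keeping the design full rank
    even when site-level predictors are collinear.  Squared z-scores are
    GIF-calibrated per variable, converted to chi-square(1) p-values, and
    FDR-adjusted per variable; the method-level candidate set is the union
    of per-variable selections at q < ``q_threshold``.
    """
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
    else:
        variables = [f"V{j + 1}" for j in range(np.asarray(X).shape[1])]
    fitmod = lfmm_ridge_fit(Y, X, config)
    Yc, Xs, U = fitmod._Yc, fitmod._Xs, fitmod.U_
    L = Yc.shape[1]
    if locus_ids is None:
        locus_ids = [f"locus{j}" for j in range(L)]
    locus_ids = list(locus_ids)

    frames = []
    selected_by_variable: dict[str, list[str]] = {}
    gifs: dict[str, float] = {}
    for kx, var in enumerate(variables):
        D = np.column_stack([Xs[:, kx], U])
        # guard against a factor column duplicating the variable
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            warnings.warn(f"dropping dependent factor columns for variable {var}")
            D = D[:, :rank]
        z = _batched_ols_z(D, Yc, col=0)
        z2 = z**2
        gif = genomic_inflation_factor(z2, df=1)
        gifs[var] = gif
        z2_cal = z2 / gif
        p = stats.chi2.sf(z2_cal, df=1)
        q = fdr_adjust(p, config.fdr_method)
        sel = q < config.q_threshold
        selected_by_variable[var] = [locus_ids[j] for j in np.flatnonzero(sel)]
        frames.append(pd.DataFrame({
            "locus_id": locus_ids, "variable": var, "stat": z2,
            "stat_calibrated": z2_cal, "p": p, "q": q, "selected": sel,
        }))
    table = pd.concat(frames, ignore_index=True)
    hit = {l for lst in selected_by_variable.values() for l in lst}
    union = [l for l in locus_ids if l in hit]
    return ScanResult(
        method="lfmm", table=table, selected=union,
        selected_by_variable=selected_by_variable, gif=gifs,
        k=config.k, converged=fitmod.converged_,
    )


class PCAdaptScan(BaseEstimator):
    """PCA-Mahalanobis outlier scan.

    Each locus is scaled to unit binomial variance, regressed on the ``K``
    leading principal components of the individuals, and its K-vector of
    regression z-scores is scored by a robust Mahalanobis distance
    (minimum covariance determinant, support fraction 0.75).  Distances are
    divided by the GIF and referred to chi-square(K).
    """

    def __init__(self, k: int = 3, support_fraction: float = 0.75, seed: int | None = None):
        self.k = k
        self.support_fraction = support_fraction
        self.seed = seed

    def fit(self, G):
        Ga = np.asarray(G, dtype=float)
        if np.isnan(Ga).any():
            raise ValueError("G must be complete (impute first)")
        n, L = Ga.shape
        if not 1 <= self.k < min(n, L):
            raise ValueError(f"k={self.k} out of range for {n} x {L} matrix")
        phat = Ga.mean(axis=0) / 2.0
        scale = np.sqrt(2.0 * phat * (1.0 - phat))
        scale[scale == 0] = 1.0
        Z = (Ga - 2.0 * phat) / scale

        u, s, _ = np.linalg.svd(Z, full_matrices=False)
        pcs = u[:, : self.k]  # orthonormal individual scores
        coef = pcs.T @ Z  # k x L (orthonormal design => OLS coefficients)
        resid = Z - pcs @ coef
        dof = max(n - self.k - 1, 1)
        sigma = np.sqrt(np.maximum((resid**2).sum(axis=0) / dof, 1e-300))
        zscores = (coef / sigma).T  # L x k

        if self.k == 1:
            d2 = zscores[:, 0] ** 2 / np.var(zscores[:, 0], ddof=0)
        else:
            try:
                mcd = MinCovDet(
                    support_fraction=self.support_fraction,
                    random_state=np.random.RandomState(self.seed if self.seed is not None else 0),
                ).fit(zscores)
                d2 = mcd.mahalanobis(zscores)
            except Exception:  # singular robust covariance
                warnings.warn("robust covariance failed; falling back to sample covariance")
                mu = zscores.mean(axis=0)
                cov = np.cov(zscores.T)
                d2 = np.einsum(
                    "ij,jk,ik->i", zscores - mu, np.linalg.pinv(np.atleast_2d(cov)), zscores - mu
                )
        self.zscores_ = zscores
        self.stat_ = np.asarray(d2, dtype=float)
        self.gif_ = genomic_inflation_factor(self.stat_, df=self.k)
        self.stat_calibrated_ = self.stat_ / self.gif_
        self.pvalues_ = stats.chi2.sf(self.stat_calibrated_, df=self.k)
        return self


def pcadapt_scan(G, config: ScanConfig, locus_ids=None) -> ScanResult:
    """Run the PCA-Mahalanobis scan and select outliers at q < ``q_threshold``."""
    model = PCAdaptScan(k=config.k, seed=config.seed).fit(G)
    L = model.stat_.size
    if locus_ids is None:
        locus_ids = [f"locus{j}" for j in range(L)]
    locus_ids = list(locus_ids)
    q = fdr_adjust(model.pvalues_, config.fdr_method)
    sel = q < config.q_threshold
    table = pd.DataFrame({
        "locus_id": locus_ids, "variable": None, "stat": model.stat_,
        "stat_calibrated": model.stat_calibrated_, "p": model.pvalues_,
        "q": q, "selected": sel,
    })
    return ScanResult(
        method="pcadapt", table=table,
        selected=[locus_ids[j] for j in np.flatnonzero(sel)],
        gif=model.gif_, k=config.k,
    )
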