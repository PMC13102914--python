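"""Redundancy analysis (RDA): constrained ordination with permutation tests.

RDA regresses a multivariate response (genotype dosages, or site-level
allele frequencies) on environmental predictors and ordinates the fitted
values.  The canonical eigenvalues partition the constrained inertia;
per-axis significance comes from a sequential permutation test (each axis
tested with the preceding axes partialled out of both response and
predictors), and candidate loci are those whose loadings on any significant
axis fall more than ``k`` standard deviations from the mean loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator

__all__ = [
    "RDA",
    "fit_rda",
    "permutation_axis_test",
    "rda_outlier_loci",
    "assign_top_variable",
    "rda_variance_test",
    "VariableAssignment",
]


def _as_2d(a, name: str) -> tuple[np.ndarray, list]:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), list(a.columns)
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    return arr, list(range(arr.shape[1]))


class RDA(BaseEstimator):
    """Redundancy analysis estimator.

    Parameters
    ----------
    scale_predictors:
        Standardize predictor columns to unit variance (recommended when
        variables carry heterogeneous units).
    svd_tol:
        Relative singular-value cutoff below which canonical axes are
        treated as null.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_ : canonical eigenvalues (variance scale, divisor n-1)
    loadings_ : loci x axes response loadings (right singular vectors)
    scores_ : row scores on the canonical axes
    total_inertia_, constrained_inertia_, residual_inertia_
    r_squared_, adjusted_r_squared_
    rank_ : effective predictor rank; dropped_predictors_ : aliased columns
    """

    def __init__(self, scale_predictors: bool = True, svd_tol: float = 1e-9):
        self.scale_predictors = scale_predictors
        self.svd_tol = svd_tol

    def fit(self, X, Y):
        Xa, xcols = _as_2d(X, "X")
        Ya, ycols = _as_2d(Y, "Y")
        if Xa.shape[0] != Ya.shape[0]:
            raise ValueError("X and Y must have aligned rows")
        n = Xa.shape[0]
        Yc = Ya - Ya.mean(axis=0)
        Xc = Xa - Xa.mean(axis=0)
        if self.scale_predictors:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xc = Xc / sd

        Q, R, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int((diag > max(tol, 1e-12)).sum())
        self.dropped_predictors_ = [xcols[k] for k in piv[rank:]]
        self.kept_predictors_ = [xcols[k] for k in piv[:rank]]
        if self.dropped_predictors_:
            warnings.warn(
                f"rank-deficient predictors; dropped collinear columns {self.dropped_predictors_}"
            )
        if rank == 0:
            raise ValueError("predictor matrix has rank 0")
        if n <= rank + 1:
            raise ValueError(
                f"need n > rank(X) + 1 rows for adjusted R^2 (n={n}, rank={rank})"
            )
        Qr = Q[:, :rank]

        fitted = Qr @ (Qr.T @ Yc)
        U, s, Vt = np.linalg.svd(fitted / np.sqrt(n - 1), full_matrices=False)
        keep = s > self.svd_tol * (s[0] if s.size and s[0] > 0 else 1.0)
        k = int(min(keep.sum(), rank, n - 1, Yc.shape[1]))
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        loadings = Vt.T
        scores = U * s
        # deterministic axis orientation: largest-|loading| locus positive
        for a in range(k):
            j = int(np.argmax(np.abs(loadings[:, a])))
            if loadings[j, a] < 0:
                loadings[:, a] *= -1.0
                scores[:, a] *= -1.0
                U[:, a] *= -1.0

        self.n_, self.rank_ = n, rank
        self.response_columns_ = ycols
        self.eigenvalues_ = s**2
        self.loadings_ = loadings
        self.scores_ = scores
        self.total_inertia_ = float((Yc**2).sum() / (n - 1))
        self.constrained_inertia_ = float(self.eigenvalues_.sum())
        self.residual_inertia_ = self.total_inertia_ - self.constrained_inertia_
        if self.total_inertia_ > 0:
            self.r_squared_ = self.constrained_inertia_ / self.total_inertia_
        else:
            self.r_squared_ = 0.0
        self.adjusted_r_squared_ = 1.0 - (1.0 - self.r_squared_) * (n - 1) / (n - rank - 1)
        # internals reused by the permutation tests
        self._Yc = Yc
        self._Q = Qr
        self._U = U
        return self

    @property
    def n_axes_(self) -> int:
        return len(self.eigenvalues_)


def fit_rda(Y, X, scale_predictors: bool = True) -> RDA:
    """Fit an RDA of response ``Y`` (rows x loci) on predictors ``X``."""
    return RDA(scale_predictors=scale_predictors).fit(X, Y)


def _seq_stage(model: RDA, i: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Response and predictor basis with canonical axes < i partialled out."""
    Yc, Q, U = model._Yc, model._Q, model._U
    if i == 0:
        Yres, Qraw = Yc, Q
    else:
        W = U[:, :i]
        Yres = Yc - W @ (W.T @ Yc)
        Qraw = Q - W @ (W.T @ Q)
    Qres = scipy.linalg.orth(Qraw, rcond=1e-10)
    return Yres, Qres, float((Yres**2).sum())


def _stage_f(M: np.ndarray, tot2: float, n: int, df_res: int) -> float:
    """Pseudo-F of the leading axis from the projected response M = Q^T Y."""
    sv = scipy.linalg.svdvals(M)
    lam1 = sv[0] ** 2 / (n - 1) if sv.size else 0.0
    resid = (tot2 - (sv**2).sum()) / (n - 1)
    if resid <= 0:
        return np.inf if lam1 > 0 else 0.0
    return lam1 / (resid / df_res)


def permutation_axis_test(
    model: RDA, Y=None, X=None, n_perm: int = 1000, seed=None, alpha: float = 0.05
) -> np.ndarray:
    """Sequential by-axis permutation test of the canonical axes.

    Axis ``i`` is tested after residualizing both the response and the
    predictor basis on the preceding canonical axes; its pseudo-F is
    compared against ``n_perm`` row permutations of the residualized
    response, giving p = (exceedances + 1) / (n_perm + 1).  ``Y``/``X`` are
    accepted for interface symmetry but the fitted model's internal matrices
    are used.  Results are stored on the model as ``axis_pvalues_`` and
    ``significant_axes_`` (p <= ``alpha``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_
    pvals = np.ones(model.n_axes_)
    for i in range(model.n_axes_):
        Yres, Qres, tot2 = _seq_stage(model, i)
        df_res = max(n - 1 - Qres.shape[1] - i, 1)
        f_obs = _stage_f(Qres.T @ Yres, tot2, n, df_res)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            # Q^T P Y computed by permuting the (small) basis instead of Y
            f_b = _stage_f(Qres[perm].T @ Yres, tot2, n, df_res)
            if f_b >= f_obs - 1e-12:
                count += 1
        pvals[i] = (count + 1) / (n_perm + 1)
    model.axis_pvalues_ = pvals
    model.significant_axes_ = np.flatnonzero(pvals <= alpha)
    return pvals


def rda_outlier_loci(
    model: RDA, significant_axes=None, k_sd: float = 3.0
) -> np.ndarray:
    """Loci loading more than ``k_sd`` SD from the mean on any significant axis.

    The test is two-sided and the union across significant axes is returned
    (as integer locus indices into the response columns).  With no
    significant axis, or a degenerate zero-SD loading distribution, the set
    is empty.
    """
    if significant_axes is None:
        significant_axes = getattr(model, "significant_axes_", None)
        if significant_axes is None:
            raise ValueError("run permutation_axis_test first or pass significant_axes")
    significant_axes = np.asarray(significant_axes, dtype=int)
    if significant_axes.size == 0:
        warnings.warn("no significant axes: empty outlier set")
        return np.array([], dtype=int)
    mask = np.zeros(model.loadings_.shape[0], dtype=bool)
    for a in significant_axes:
        load = model.loadings_[:, a]
        mu, sd = load.mean(), load.std(ddof=0)
        if sd == 0:
            continue
        mask |= np.abs(load - mu) > k_sd * sd
    return np.flatnonzero(mask)


@dataclass
class VariableAssignment:
    locus_id: str
    variable: str | None
    r: float
    tie: bool


def assign_top_variable(loci, geno_dosage, env_per_individual) -> pd.DataFrame:
    """Assign each locus the environmental variable it correlates with most.

    ``geno_dosage`` is a complete (imputed) individuals x loci array aligned
    with ``env_per_individual`` rows.  For each locus the Pearson r against
    every variable is computed; the variable with the largest |r| wins, with
    the signed r stored.  Ties (|r| differences below 1e-12) break
    lexicographically by variable name and are flagged; zero-variance loci
    get no assignment and are flagged.
    """
    G, _ = _as_2d(geno_dosage, "geno_dosage")
    E, vnames = _as_2d(env_per_individual, "env")
    loci = list(loci)
    if G.shape[1] != len(loci):
        raise ValueError("dosage columns must match loci")
    if G.shape[0] != E.shape[0]:
        raise ValueError("dosage and environment rows must align")
    order = np.argsort(vnames)
    E = E[:, order]
    vnames = [vnames[k] for k in order]
    n = G.shape[0]

    Gc = G - G.mean(axis=0)
    Ec = E - E.mean(axis=0)
    gsd = Gc.std(axis=0, ddof=0)
    esd = Ec.std(axis=0, ddof=0)
    esd[esd == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Gc.T @ Ec) / n / np.outer(gsd, esd)

    rows = []
    for j, lid in enumerate(loci):
        if gsd[j] == 0 or np.all(np.isnan(R[j])):
            rows.append((lid, None, np.nan, True))
            continue
        absr = np.abs(R[j])
        absr = np.where(np.isnan(absr), -np.inf, absr)
        best = int(np.argmax(absr))  # argmax keeps the lexicographically first on ties
        tie = bool(np.sum(absr >= absr[best] - 1e-12) > 1)
        rows.append((lid, vnames[best], float(R[j, best]), tie))
    return pd.DataFrame(rows, columns=["locus_id", "variable", "r", "tie"])


def rda_variance_test(Y, X, n_perm: int = 999, seed=None) -> dict:
    """Global permutation test of the variance explained by the full constraint.

    Returns R^2, adjusted R^2 and the permutation p-value of the global
    pseudo-F (all canonical axes jointly), with p = (exceedances + 1) /
    (n_perm + 1) under row permutations of the response.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model = fit_rda(Y, X)
    rng = np.random.default_rng(seed)
    n, r = model.n_, model.rank_
    Yc, Q = model._Yc, model._Q
    tot2 = float((Yc**2).sum())
    df_res = n - 1 - r

    def global_f(M: np.ndarray) -> float:
        constr = (M**2).sum()
        resid = tot2 - constr
        if resid <= 0:
            return np.inf if constr > 0 else 0.0
        return (constr / r) / (resid / df_res)

    f_obs = global_f(Q.T @ Yc)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if global_f(Q[perm].T @ Yc) >= f_obs - 1e-12:
            count += 1
    return {
        "R2": model.r_squared_,
        "adjusted_R2": model.adjusted_r_squared_,
        "p_global": (count + 1) / (n_perm + 1),
        "n": n,
        "rank": r,
        "model": model,
    }
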