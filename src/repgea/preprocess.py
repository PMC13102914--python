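"""Environment pruning/PCA and genotype quality control.

Environment variables are pruned for collinearity before association testing
(greedy removal of the hub of any |r| >= 0.8 pair), then optionally
summarised by PCA to compare landscapes.  Genotype matrices pass through the
standard post-calling filter cascade — genotype-level depth/quality masking,
per-locus missingness, minor-allele frequency and an exact Hardy-Weinberg
test — before imputation for the ordination-based scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .datatypes import FilterThresholds, GenotypeMatrix

__all__ = [
    "prune_correlated_env",
    "environment_pca",
    "hwe_exact_test",
    "filter_genotypes",
    "impute_missing",
    "site_allele_freq",
    "FilterReport",
]


def prune_correlated_env(
    env: pd.DataFrame, r_max: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop variables until all pairwise |Pearson r| < ``r_max``.

    While any pair correlates at or above the threshold, the strongest pair
    is located and the member with the larger mean absolute correlation to
    all remaining variables (the "hub") is removed; ties break
    lexicographically.  Zero-variance variables, whose correlation is
    undefined, are dropped first with a warning.

    Returns the pruned table and the dropped variable names in removal order.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    work = env.copy()
    dropped: list[str] = []
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        warnings.warn(f"zero-variance variables dropped before pruning: {constant}")
        dropped.extend(constant)
        work = work.drop(columns=constant)
    while work.shape[1] >= 2:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() < r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = sorted((corr.columns[i], corr.columns[j]))
        mean_abs = corr.mean(axis=1) * corr.shape[1] / (corr.shape[1] - 1)
        victim = a if mean_abs[a] >= mean_abs[b] else b
        dropped.append(victim)
        work = work.drop(columns=victim)
    return work, dropped


def environment_pca(env_combined: pd.DataFrame) -> dict:
    """PCA of the (centered, unit-variance scaled) site x variable table.

    Returns a dict with ``scores`` (site x PC), ``loadings`` (variable x PC)
    and ``explained`` (variance fractions over all components, summing to 1).
    """
    if env_combined.shape[0] < 2:
        raise ValueError("PCA needs at least 2 sites")
    X = env_combined.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    total = pca.explained_variance_.sum()
    return {
        "scores": pd.DataFrame(scores, index=env_combined.index, columns=cols),
        "loadings": pd.DataFrame(
            pca.components_.T, index=env_combined.columns, columns=cols
        ),
        "explained": pd.Series(pca.explained_variance_ / total, index=cols),
    }


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test on one locus's genotype counts.

    Conditional on the observed allele counts, the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard exact HWE test).  Monomorphic loci return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = n_Aa + 2 * n_aa  # minor-allele copies (relabel below)
    n_A = n_Aa + 2 * n_AA
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # all heterozygote counts sharing the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        - gammaln(2 * n + 1)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


@dataclass
class FilterReport:
    """Counts of genotypes masked and loci removed at each filter step."""

    genotypes_masked: int = 0
    removed_missing: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_loci_in: int = 0
    n_loci_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _maf(dosage: np.ndarray) -> np.ndarray:
    """Per-locus minor-allele frequency from non-missing dosages."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_genotypes(
    geno: GenotypeMatrix, t: FilterThresholds = FilterThresholds()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the post-calling filter cascade, in order.

    1. mask genotypes with depth < ``min_depth`` or quality <
       ``min_genotype_quality`` (skipped when those fields are absent);
    2. drop loci with missing fraction strictly above ``max_missing``;
    3. drop loci with MAF strictly below ``maf_min``;
    4. drop loci with exact-HWE p below ``hwe_alpha`` (deviating loci; the
       direction flips if ``hwe_remove_deviating`` is False).
    """
    report = FilterReport(n_loci_in=geno.n_loci)
    g = geno.copy()

    dosage = g.dosage
    if g.depth is not None or g.qual is not None:
        bad = np.zeros(dosage.shape, dtype=bool)
        if g.depth is not None:
            bad |= g.depth < t.min_depth
        if g.qual is not None:
            bad |= g.qual < t.min_genotype_quality
        bad &= ~np.isnan(dosage)
        report.genotypes_masked = int(bad.sum())
        dosage = dosage.copy()
        dosage[bad] = np.nan
        g = GenotypeMatrix(dosage, g.loci, g.samples, depth=g.depth, qual=g.qual)

    miss_frac = np.isnan(g.dosage).mean(axis=0)
    keep = miss_frac <= t.max_missing
    report.removed_missing = int((~keep).sum())
    g = _drop(g, keep, "missingness")

    keep = _maf(g.dosage) >= t.maf_min
    report.removed_maf = int((~keep).sum())
    g = _drop(g, keep, "MAF")

    hwe_p = np.array([
        hwe_exact_test(
            int(np.nansum(col == 0)), int(np.nansum(col == 1)), int(np.nansum(col == 2))
        )
        for col in g.dosage.T
    ])
    if t.hwe_remove_deviating:
        keep = hwe_p >= t.hwe_alpha
    else:
        keep = hwe_p <= t.hwe_alpha
    report.removed_hwe = int((~keep).sum())
    g = _drop(g, keep, "HWE")

    report.n_loci_out = g.n_loci
    return g, report


def _drop(g: GenotypeMatrix, keep: np.ndarray, step: str) -> GenotypeMatrix:
    if not keep.any():
        raise ValueError(f"no loci left after the {step} filter step")
    if keep.all():
        return g
    return g.subset_loci(keep)


def impute_missing(geno: GenotypeMatrix, strategy: str = "most_frequent") -> GenotypeMatrix:
    """Replace missing dosages per locus by the modal or mean dosage.

    ``most_frequent`` preserves integer dosages (ties break toward the
    smaller dosage); ``mean`` allows fractional values.
    """
    if strategy not in ("most_frequent", "mean"):
        raise ValueError(f"unknown strategy {strategy!r}")
    dosage = geno.dosage.copy()
    miss = np.isnan(dosage)
    if not miss.any():
        return geno.copy()
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        raise ValueError(f"{fully_missing.sum()} loci are fully missing; filter first")
    for j in np.flatnonzero(miss.any(axis=0)):
        col = dosage[:, j]
        obs = col[~np.isnan(col)]
        if strategy == "most_frequent":
            counts = np.bincount(obs.astype(int), minlength=3)
            fill = float(np.argmax(counts))  # argmax takes the smaller dosage on ties
        else:
            fill = float(obs.mean())
        col[np.isnan(col)] = fill
    return GenotypeMatrix(dosage, geno.loci.copy(), geno.samples)


def site_allele_freq(geno: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Site x locus alternate-allele frequency matrix.

    Frequency = (sum of dosages at the site) / (2 x non-missing calls).
    A site with zero non-missing calls at a locus yields NaN.
    """
    order = pd.Index(samples["individual_id"])
    if not order.equals(geno.samples):
        raise ValueError("sample table order must match genotype matrix")
    site = samples["site_id"].to_numpy()
    out = {}
    for s in pd.unique(site):
        rows = geno.dosage[site == s]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[s] = np.nanmean(rows, axis=0) / 2.0
    freq = pd.DataFrame.from_dict(out, orient="index", columns=geno.locus_ids)
    freq.index.name = "site_id"
    return freq
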