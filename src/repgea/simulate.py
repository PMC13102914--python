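"""Synthetic two-landscape studies with ground truth.

The generator emulates the sampling design the analysis assumes: two
independent landscapes with a handful of sampling sites each, partially
correlated climatic and water-physicochemistry variables measured per site,
neutral SNPs structured into a few genetic clusters (Balding-Nichols model),
and adaptive SNPs whose site-level allele frequencies track one driving
environmental variable on the logit scale.  A fraction of adaptive genes is
shared between landscapes — the repeated-adaptation signal the downstream
statistics are designed to detect.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning (one child stream per landscape per
stage), so a study is bitwise reproducible from its configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import GenotypeMatrix, Landscape, Study

__all__ = [
    "EnvSpec",
    "SimConfig",
    "SyntheticTruth",
    "default_env_spec",
    "simulate_environment",
    "simulate_genotypes",
    "simulate_replicate_pair",
]

TERM_CATEGORIES = ("biological_process", "cellular_component", "pathway")


@dataclass(frozen=True)
class EnvSpec:
    """Names, site-level means/SDs and correlation matrix of the environment."""

    names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    corr: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.names)
        corr = np.asarray(self.corr, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-8:
            raise ValueError(
                f"correlation matrix not positive semi-definite (min eigenvalue {w.min():.3g})"
            )
        if len(self.means) != p or len(self.sds) != p:
            raise ValueError("means/sds length must match names")
        object.__setattr__(self, "corr", corr)

    @property
    def n_variables(self) -> int:
        return len(self.names)

    def uncorrelated_names(self, r_max: float = 0.8) -> list[str]:
        """Variables whose requested correlation to every other is < r_max."""
        off = np.abs(self.corr - np.eye(self.n_variables))
        keep = off.max(axis=1) < r_max
        return [n for n, k in zip(self.names, keep) if k]


def default_env_spec() -> EnvSpec:
    """Ten site-level variables: climate plus water physicochemistry.

    AT ambient temperature (degC), RH relative humidity (%), SR solar
    radiation, EVA evapotranspiration (raster-native units), WT water
    temperature (degC), OA dissolved-oxygen availability, pH, and ppm of
    potassium (K), nitrates (NO) and sodium (Na).  Correlations are induced by
    two latent factors — a heat factor (AT, WT, EVA, SR high; RH, OA low) and
    a runoff-pollution factor (pH, NO, K, Na) — which guarantees a positive
    semi-definite matrix and makes the pH-NO pair correlate above the 0.8
    pruning threshold, as field data sets of this kind typically do.
    """
    names = ("AT", "EVA", "K", "NO", "Na", "OA", "RH", "SR", "WT", "pH")
    # latent factor loadings: column 0 = heat, column 1 = runoff chemistry
    lam = {
        "AT": (0.75, 0.0),
        "EVA": (0.65, 0.0),
        "K": (0.0, 0.60),
        "NO": (0.0, 0.90),
        "Na": (0.0, 0.55),
        "OA": (-0.35, 0.0),
        "RH": (-0.60, 0.0),
        "SR": (0.55, 0.0),
        "WT": (0.60, 0.0),
        "pH": (0.0, 0.95),
    }
    L = np.array([lam[n] for n in names])
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    means = {
        "AT": 28.0, "EVA": 120.0, "K": 18.0, "NO": 4.0, "Na": 25.0,
        "OA": 6.5, "RH": 70.0, "SR": 16000.0, "WT": 26.0, "pH": 7.8,
    }
    sds = {
        "AT": 2.5, "EVA": 15.0, "K": 6.0, "NO": 1.5, "Na": 8.0,
        "OA": 1.2, "RH": 8.0, "SR": 1200.0, "WT": 2.0, "pH": 0.4,
    }
    return EnvSpec(
        names=names,
        means=tuple(means[n] for n in names),
        sds=tuple(sds[n] for n in names),
        corr=corr,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a simulated two-landscape replicate pair."""

    n_sites_per_landscape: tuple[int, int] = (8, 7)
    #: per-landscape individuals per site; an int applies to both landscapes
    n_individuals_per_site: tuple[int, int] | int = (15, 9)
    n_clusters: tuple[int, int] = (3, 2)
    n_neutral_loci: int = 2950
    n_adaptive_loci: int = 50
    n_loci_per_contig: tuple[int, int] = (1, 3)
    shared_gene_fraction: float = 0.5
    effect_size_beta: float = 2.0
    fst_drift: float = 0.1
    missing_rate: float = 0.05
    env_spec: EnvSpec = field(default_factory=default_env_spec)
    n_terms: int = 30
    n_enriched_terms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        n_ind = self.n_individuals_per_site
        if isinstance(n_ind, int):
            n_ind = (n_ind, n_ind)
            object.__setattr__(self, "n_individuals_per_site", n_ind)
        counts = (
            *self.n_sites_per_landscape, *n_ind,
            *self.n_clusters, self.n_neutral_loci, self.n_terms,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if self.n_adaptive_loci < 0:
            raise ValueError("n_adaptive_loci must be >= 0")
        lo, hi = self.n_loci_per_contig
        if not (1 <= lo <= hi):
            raise ValueError("n_loci_per_contig must be an increasing range from >= 1")
        for name in ("shared_gene_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.fst_drift < 1.0:
            raise ValueError("fst_drift must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for a simulated study.

    ``loci`` has one row per locus per landscape (``locus_id, landscape_id,
    is_adaptive, driving_variable, beta``); ``driving_variable`` is None iff
    the locus is neutral in that landscape.  ``genes`` flags per-landscape
    adaptive genes and the shared subset; ``terms`` flags enriched terms.
    """

    loci: pd.DataFrame
    genes: pd.DataFrame
    terms: pd.DataFrame
    clamped_frequencies: int = 0

    def adaptive_loci(self, landscape_id: str) -> list[str]:
        sub = self.loci[(self.loci["landscape_id"] == landscape_id) & self.loci["is_adaptive"]]
        return sub["locus_id"].tolist()

    def driving_variable_map(self, landscape_id: str) -> dict[str, str]:
        sub = self.loci[(self.loci["landscape_id"] == landscape_id) & self.loci["is_adaptive"]]
        return dict(zip(sub["locus_id"], sub["driving_variable"]))

    def shared_adaptive_genes(self) -> list[str]:
        return self.genes.loc[self.genes["is_shared_adaptive"], "gene"].tolist()


def simulate_environment(
    n_sites: int,
    env_spec: EnvSpec,
    seed,
    site_prefix: str = "S",
) -> pd.DataFrame:
    """Draw a site x variable environment table from the spec's Gaussian model.

    The correlation matrix may be singular (e.g. a requested correlation of
    exactly 1.0): sampling uses the eigendecomposition square root, so
    perfectly correlated variables come out identical up to affine scaling.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(env_spec.corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_sites, env_spec.n_variables)) @ root.T
    values = np.asarray(env_spec.means) + np.asarray(env_spec.sds) * z
    index = pd.Index(
        [f"{site_prefix}{i + 1:02d}" for i in range(n_sites)], name="site_id"
    )
    return pd.DataFrame(values, index=index, columns=list(env_spec.names))


def _balding_nichols_freqs(rng, p_anc: np.ndarray, n_clusters: int, fst: float) -> np.ndarray:
    """Cluster allele frequencies, shape (n_clusters, n_loci)."""
    if fst < 1e-9:
        return np.tile(p_anc, (n_clusters, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_clusters, len(p_anc)))


def _default_locus_table(n_loci: int, loci_per_contig: tuple[int, int], rng) -> pd.DataFrame:
    rows = []
    contig = 0
    while len(rows) < n_loci:
        contig += 1
        size = int(rng.integers(loci_per_contig[0], loci_per_contig[1] + 1))
        for k in range(size):
            if len(rows) >= n_loci:
                break
            name = f"ctg{contig:05d}"
            pos = 100 * (k + 1)
            rows.append((f"{name}:{pos}", name, pos))
    df = pd.DataFrame(rows, columns=["locus_id", "contig", "pos"])
    df["ref"] = "A"
    df["alt"] = "T"
    return df


def simulate_genotypes(
    samples: pd.DataFrame,
    env: pd.DataFrame,
    config: SimConfig,
    seed,
    *,
    n_clusters: Optional[int] = None,
    loci: Optional[pd.DataFrame] = None,
    adaptive_plan: Optional[dict[int, tuple[str, float]]] = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, int]:
    """Simulate one landscape's genotype matrix.

    Neutral loci: ancestral frequency ~ Uniform(0.1, 0.9), cluster
    frequencies Balding-Nichols with F = ``config.fst_drift``, genotypes
    Binomial(2, cluster frequency).  Adaptive loci (``adaptive_plan`` maps
    locus index -> (driving variable, beta)): site frequency is
    logit(ancestral) + beta x standardized driving variable, clamped to
    [0.01, 0.99]; genotypes Binomial(2, site frequency).  Entries are masked
    missing at ``config.missing_rate``.

    Returns the matrix, a per-locus truth table for this landscape, and the
    number of site frequencies clamped at the boundary.
    """
    unknown = set(samples["site_id"]) - set(env.index)
    if unknown:
        raise ValueError(f"samples reference sites absent from env: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if n_clusters is None:
        n_clusters = config.n_clusters[0]
    if loci is None:
        loci = _default_locus_table(
            config.n_neutral_loci + config.n_adaptive_loci, config.n_loci_per_contig, rng
        )
    adaptive_plan = adaptive_plan or {}
    n_loci = len(loci)
    sites = list(env.index)
    site_cluster = {s: i % n_clusters for i, s in enumerate(sites)}
    site_of = samples["site_id"].to_numpy()
    n_ind = len(samples)

    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    cluster_freq = _balding_nichols_freqs(rng, p_anc, n_clusters, config.fst_drift)

    # per-site frequency per locus: neutral loci take their cluster's
    # frequency; adaptive loci follow the logit-linear environmental model
    site_freq = np.empty((len(sites), n_loci))
    for si, s in enumerate(sites):
        site_freq[si] = cluster_freq[site_cluster[s]]
    n_clamped = 0
    for j, (variable, beta) in adaptive_plan.items():
        x = env[variable].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        f = expit(logit(p_anc[j]) + beta * z)
        clamped = (f < 0.01) | (f > 0.99)
        n_clamped += int(clamped.sum())
        site_freq[:, j] = np.clip(f, 0.01, 0.99)

    site_index = {s: i for i, s in enumerate(sites)}
    ind_site_idx = np.array([site_index[s] for s in site_of])
    dosage = rng.binomial(2, site_freq[ind_site_idx, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    gm = GenotypeMatrix(
        dosage=dosage,
        loci=loci.reset_index(drop=True),
        samples=pd.Index(samples["individual_id"]),
    )
    lid = samples["landscape_id"].iloc[0]
    truth = pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy(),
            "landscape_id": lid,
            "is_adaptive": [j in adaptive_plan for j in range(n_loci)],
            "driving_variable": [
                adaptive_plan[j][0] if j in adaptive_plan else None for j in range(n_loci)
            ],
            "beta": [adaptive_plan[j][1] if j in adaptive_plan else 0.0 for j in range(n_loci)],
        }
    )
    return gm, truth, n_clamped


def _adaptive_layout(config: SimConfig, rng) -> tuple[pd.DataFrame, dict, dict, list[str]]:
    """Lay adaptive loci onto contigs/genes, shared genes first.

    Each adaptive gene is one contig carrying two SNPs.  A shared gene holds
    one SNP adaptive in each landscape; a landscape-unique gene holds two
    SNPs adaptive in that landscape only.  Solving
    ``n_adaptive = s + 2u`` with ``s = f * (total adaptive genes)`` gives
    ``s = round(f * n_adaptive / (2 - f))`` shared genes.
    """
    n_ad = config.n_adaptive_loci
    f = config.shared_gene_fraction
    if n_ad == 0:
        return pd.DataFrame(columns=["locus_id", "contig", "pos", "ref", "alt"]), {}, {}, []
    s = int(round(f * n_ad / (2.0 - f))) if f > 0 else 0
    if f > 0 and s == 0:
        warnings.warn("shared_gene_fraction too small for any shared gene; none generated")
    u = (n_ad - s) // 2
    leftover = n_ad - s - 2 * u  # 0 or 1 extra single-SNP unique gene

    rows: list[tuple] = []
    plan1: dict[int, tuple[str, float]] = {}
    plan2: dict[int, tuple[str, float]] = {}
    shared_genes: list[str] = []
    drive_pool = default_driving_pool(config.env_spec)
    contig_no = 0

    def new_contig() -> str:
        nonlocal contig_no
        contig_no += 1
        return f"adp{contig_no:05d}"

    def draw_effect() -> tuple[str, float]:
        var = str(rng.choice(drive_pool))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return var, sign * config.effect_size_beta

    def add_locus(contig: str, k: int, plan: Optional[dict], effect) -> None:
        pos = 100 * (k + 1)
        rows.append((f"{contig}:{pos}", contig, pos, "A", "T"))
        if plan is not None:
            plan[len(rows) - 1] = effect

    for _ in range(s):
        contig = new_contig()
        shared_genes.append(contig)
        effect = draw_effect()  # the gene responds to one pressure in both landscapes
        add_locus(contig, 0, plan1, effect)
        add_locus(contig, 1, plan2, effect)
    for plan in (plan1, plan2):
        for _ in range(u):
            contig = new_contig()
            effect = draw_effect()
            add_locus(contig, 0, plan, effect)
            add_locus(contig, 1, plan, effect)
        if leftover:
            contig = new_contig()
            add_locus(contig, 0, plan, draw_effect())

    loci = pd.DataFrame(rows, columns=["locus_id", "contig", "pos", "ref", "alt"])
    return loci, plan1, plan2, shared_genes


def default_driving_pool(env_spec: EnvSpec) -> list[str]:
    """Variables eligible to drive adaptive loci.

    Variables requested to correlate >= 0.8 with another are excluded so the
    true driver is identifiable by a maximum-correlation assignment (the
    correlated member would otherwise be pruned before association testing).
    """
    pool = env_spec.uncorrelated_names(r_max=0.8)
    if not pool:
        raise ValueError("env_spec leaves no variable eligible to drive adaptation")
    return pool


def _simulate_terms(config: SimConfig, genes: list[str], shared_genes: list[str], rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    n_terms = config.n_terms
    n_enr = min(config.n_enriched_terms, n_terms)
    term_ids = [f"T{i + 1:04d}" for i in range(n_terms)]
    enriched = set(term_ids[:n_enr])
    rows = []
    background_terms = term_ids[n_enr:] or term_ids
    for g in genes:
        k = int(rng.integers(1, 3))
        for t in rng.choice(background_terms, size=min(k, len(background_terms)), replace=False):
            rows.append((t, g))
    shared_set = set(shared_genes)
    for g in genes:
        if g in shared_set:
            if rng.random() < 0.9 and enriched:
                rows.append((str(rng.choice(sorted(enriched))), g))
        else:
            # sparse background membership keeps enriched terms non-trivial
            for t in sorted(enriched):
                if rng.random() < 0.02:
                    rows.append((t, g))
    terms = pd.DataFrame(sorted(set(rows)), columns=["term", "gene"])
    terms["category"] = [
        TERM_CATEGORIES[int(t[1:]) % len(TERM_CATEGORIES)] for t in terms["term"]
    ]
    terms = terms[["term", "category", "gene"]]
    truth_terms = pd.DataFrame({"term": term_ids, "is_enriched": [t in enriched for t in term_ids]})
    return terms, truth_terms


def simulate_replicate_pair(config: SimConfig) -> Study:
    """Simulate a full two-landscape study with ground truth attached.

    Landscapes are labelled L1 and L2 and share one locus universe (loci sit
    on a common reference), but individuals, environments and genotype draws
    are independent.  ``shared_gene_fraction`` of adaptive genes carry
    adaptive SNPs in both landscapes (different SNPs within the same gene).
    """
    ss = np.random.SeedSequence(config.seed)
    s_layout, s_env1, s_env2, s_gen1, s_gen2, s_terms = ss.spawn(6)
    rng_layout = np.random.default_rng(s_layout)

    adaptive_loci, plan1, plan2, shared_genes = _adaptive_layout(config, rng_layout)
    neutral_loci = _default_locus_table(
        config.n_neutral_loci, config.n_loci_per_contig, rng_layout
    )
    loci = pd.concat([adaptive_loci, neutral_loci], ignore_index=True)

    landscapes: dict[str, Landscape] = {}
    truth_frames = []
    n_clamped = 0
    for lid, n_sites, n_per_site, n_clust, s_env, s_gen, plan in (
        ("L1", config.n_sites_per_landscape[0], config.n_individuals_per_site[0],
         config.n_clusters[0], s_env1, s_gen1, plan1),
        ("L2", config.n_sites_per_landscape[1], config.n_individuals_per_site[1],
         config.n_clusters[1], s_env2, s_gen2, plan2),
    ):
        env = simulate_environment(n_sites, config.env_spec, s_env, site_prefix=f"{lid}_S")
        samples = pd.DataFrame(
            {
                "individual_id": [
                    f"{lid}_I{i + 1:03d}" for i in range(n_sites * n_per_site)
                ],
                "site_id": np.repeat(list(env.index), n_per_site),
                "landscape_id": lid,
            }
        )
        gm, truth_l, clamped = simulate_genotypes(
            samples, env, config, s_gen, n_clusters=n_clust, loci=loci, adaptive_plan=plan
        )
        n_clamped += clamped
        truth_frames.append(truth_l)
        landscapes[lid] = Landscape(lid, samples, env, gm)

    annotation = loci[["locus_id", "contig"]].copy()
    annotation["gene"] = annotation["contig"]  # one gene per contig by construction

    genes = sorted(annotation["gene"].unique())
    ad1 = {loci.loc[j, "contig"] for j in plan1}
    ad2 = {loci.loc[j, "contig"] for j in plan2}
    gene_truth = pd.DataFrame(
        {
            "gene": genes,
            "is_adaptive_L1": [g in ad1 for g in genes],
            "is_adaptive_L2": [g in ad2 for g in genes],
            "is_shared_adaptive": [g in set(shared_genes) for g in genes],
        }
    )
    terms, term_truth = _simulate_terms(config, genes, shared_genes, np.random.default_rng(s_terms))
    truth = SyntheticTruth(
        loci=pd.concat(truth_frames, ignore_index=True),
        genes=gene_truth,
        terms=term_truth,
        clamped_frequencies=n_clamped,
    )
    return Study(landscapes=landscapes, annotation=annotation, terms=terms, truth=truth)
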