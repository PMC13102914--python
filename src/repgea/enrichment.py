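"""Gene annotation, cross-landscape gene overlap, and over-representation.

Candidate SNPs are mapped to genes through a locus -> contig -> gene table
(one gene per locus at most).  Gene sets from the two landscapes are
intersected, and the shared genes are tested for over-represented functional
terms with a hypergeometric upper-tail test and fold enrichment
``(k/n) / (K/N)``.  A site-level allele-frequency RDA then relates the SNPs
supporting the shared enriched genes back to the environment, assigning each
SNP its top variable with a signed Pearson r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rda import RDA, assign_top_variable
from .scans import fdr_adjust

__all__ = [
    "AnnotationMap",
    "map_candidates_to_genes",
    "shared_gene_set",
    "over_representation",
    "shared_gene_gea_table",
]


@dataclass
class AnnotationMap:
    """Locus -> contig -> gene and gene -> term membership tables.

    ``annotation`` columns: locus_id, contig, gene (<= 1 gene per locus);
    ``terms`` columns: term, category, gene.
    """

    annotation: pd.DataFrame
    terms: pd.DataFrame

    def __post_init__(self) -> None:
        if self.annotation["locus_id"].duplicated().any():
            raise ValueError("each locus maps to at most one gene")
        if "category" not in self.terms.columns:
            self.terms = self.terms.assign(category="pathway")

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.annotation["locus_id"], self.annotation["gene"]))

    def background_genes(self) -> set[str]:
        return set(self.annotation["gene"].dropna())

    def term_members(self) -> dict[str, set[str]]:
        return {t: set(g["gene"]) for t, g in self.terms.groupby("term")}

    def terms_of_gene(self) -> dict[str, set[str]]:
        return {g: set(t["term"]) for g, t in self.terms.groupby("gene")}


def map_candidates_to_genes(
    candidate_loci, annotation: AnnotationMap
) -> tuple[pd.DataFrame, int]:
    """Deduplicated genes hit by candidate loci, with supporting loci.

    Returns a table (gene, n_loci, loci) and the count of candidate loci
    without an annotation.
    """
    gene_of = annotation.gene_of()
    support: dict[str, list[str]] = {}
    unmapped = 0
    for locus in candidate_loci:
        gene = gene_of.get(locus)
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            unmapped += 1
            continue
        support.setdefault(gene, []).append(locus)
    rows = [
        {"gene": g, "n_loci": len(loci), "loci": ",".join(sorted(loci))}
        for g, loci in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "n_loci", "loci"]), unmapped


def shared_gene_set(genes_L1, genes_L2) -> tuple[list[str], dict[str, int]]:
    """Intersection of the two landscapes' candidate gene sets.

    Returns the shared genes and the counts (n_L1, n_L2, n_shared) that feed
    the repeatability inputs.
    """
    s1, s2 = set(genes_L1), set(genes_L2)
    shared = sorted(s1 & s2)
    return shared, {"n_L1": len(s1), "n_L2": len(s2), "n_shared": len(shared)}


def over_representation(
    gene_list,
    background,
    annotation: AnnotationMap,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of functional terms.

    For each term with K member genes in the ``background`` (N genes) and k
    members among the n genes of ``gene_list``:
    p = P(X >= k) under hypergeometric(N, K, n) and
    fold_enrichment = (k/n) / (K/N).  q-values are FDR-adjusted across all
    tested terms; rows with q <= ``q_threshold`` are flagged significant.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    genes = set(gene_list)
    if not genes <= background:
        raise ValueError("gene_list must be a subset of the background")
    N, n = len(background), len(genes)
    rows = []
    for term, grp in annotation.terms.groupby("term"):
        members = set(grp["gene"]) & background
        K = len(members)
        if K == 0:
            continue
        hits = genes & members
        k = len(hits)
        fold = (k / n) / (K / N) if n else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term,
            "category": grp["category"].iloc[0],
            "k": k, "n": n, "K": K, "N": N,
            "fold_enrichment": fold,
            "p": p,
            "genes": ",".join(sorted(hits)),
        })
    out = pd.DataFrame(
        rows, columns=["term", "category", "k", "n", "K", "N", "fold_enrichment", "p", "genes"]
    )
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= q_threshold
        out = out.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def enriched_genes(enrichment_rows: pd.DataFrame) -> list[str]:
    """Union of genes appearing in any significant term."""
    sig = enrichment_rows[enrichment_rows["significant"]]
    genes: set[str] = set()
    for cell in sig["genes"]:
        if cell:
            genes.update(cell.split(","))
    return sorted(genes)


def shared_gene_gea_table(
    shared_genes,
    site_freqs: pd.DataFrame,
    env: pd.DataFrame,
    annotation: AnnotationMap,
) -> pd.DataFrame:
    """Site-level allele-frequency GEA of the SNPs in shared genes.

    ``site_freqs`` is the site x locus alternate-allele frequency matrix of
    one landscape and ``env`` its site x variable table.  An RDA of the
    frequencies of the SNPs supporting ``shared_genes`` on the environment
    is fitted (predictors dropped to keep the model estimable at the
    available number of sites), and each SNP is assigned its top variable
    with a signed Pearson r, joined with gene and term memberships.
    """
    shared = set(shared_genes)
    gene_of = annotation.gene_of()
    loci = [l for l in site_freqs.columns if gene_of.get(l) in shared]
    terms_of = annotation.terms_of_gene()
    if not loci:
        return pd.DataFrame(columns=["locus_id", "gene", "variable", "r", "sign", "tie", "terms"])
    Y = site_freqs[loci]
    complete = ~Y.isna().any(axis=1)
    Y = Y.loc[complete]
    X = env.loc[Y.index]
    n_sites = len(Y)
    max_pred = max(n_sites - 2, 1)
    if X.shape[1] > max_pred:
        warnings.warn(
            f"{X.shape[1]} predictors for {n_sites} sites; keeping the first {max_pred}"
        )
        X = X.iloc[:, :max_pred]
    RDA().fit(X, Y)  # ordination context; assignment below drives the table
    assign = assign_top_variable(loci, Y, X)
    rows = []
    for rec in assign.itertuples(index=False):
        gene = gene_of.get(rec.locus_id)
        rows.append({
            "locus_id": rec.locus_id,
            "gene": gene,
            "variable": rec.variable,
            "r": rec.r,
            "sign": "" if np.isnan(rec.r) else ("+" if rec.r >= 0 else "-"),
            "tie": rec.tie,
            "terms": ",".join(sorted(terms_of.get(gene, set()))),
        })
    return pd.DataFrame(rows)
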