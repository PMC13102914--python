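"""End-to-end orchestration: filters -> scans -> consensus -> repeatability.

A :class:`PipelineConfig` describes either a synthetic study (a
:class:`~repgea.simulate.SimConfig`) or file paths to a real one.  The
pipeline then runs, per landscape: environment pruning, genotype filtering,
imputation, the three outlier scans and consensus calling; and study-level:
the neutral/random comparison sets, the 14-test repeatability design, the
variable-overlap tests, gene mapping, over-representation of shared genes,
the C_hyper report and the site-level shared-gene GEA tables.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import CandidateSet, build_neutral_set, consensus_candidates
from .datatypes import FilterThresholds, Landscape, Study
from .enrichment import (
    AnnotationMap,
    enriched_genes,
    map_candidates_to_genes,
    over_representation,
    shared_gene_gea_table,
    shared_gene_set,
)
from .preprocess import (
    environment_pca,
    filter_genotypes,
    impute_missing,
    prune_correlated_env,
    site_allele_freq,
)
from .rda import assign_top_variable, fit_rda, permutation_axis_test, rda_outlier_loci
from .repeatability import (
    RepeatabilityInputs,
    repeatability_report,
    repeated_selection_tests,
    variable_overlap_test,
)
from .scans import ScanConfig, lfmm_scan, pcadapt_scan
from .simulate import SimConfig, simulate_replicate_pair

__all__ = ["PipelineConfig", "load_study", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run: inputs, thresholds, seed."""

    sim: Optional[SimConfig] = None
    paths: Optional[dict] = None  # {"L1": {"vcf","samples","env"}, "L2": {...}, "annotation","terms"}
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    scan_k: Optional[dict[str, int]] = None  # latent factors per landscape
    r_max: float = 0.8
    min_methods: int = 2
    n_perm: int = 999
    q_threshold: float = 0.01
    ora_q_threshold: float = 0.05
    rda_outlier_sd: float = 3.0
    axis_alpha: float = 0.05
    impute_strategy: str = "most_frequent"
    fdr_method: str = "benjamini_hochberg"
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.paths is None):
            raise ValueError("exactly one of sim / paths must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        return cls(sim=sim, thresholds=thresholds, **raw)

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["env_spec"] = {
                "names": list(self.sim.env_spec.names),
                "corr": self.sim.env_spec.corr.tolist(),
            }
        return d


def load_study(config: PipelineConfig) -> Study:
    """Materialize the Study from synthetic or file-based inputs."""
    if config.sim is not None:
        return simulate_replicate_pair(config.sim)
    from .io import read_landscape

    paths = config.paths
    lids = [k for k in paths if k not in ("annotation", "terms")]
    landscapes = {
        lid: read_landscape(
            lid, paths[lid]["vcf"], paths[lid]["samples"], paths[lid]["env"]
        )
        for lid in lids
    }
    return Study(
        landscapes=landscapes,
        annotation=pd.read_csv(paths["annotation"]),
        terms=pd.read_csv(paths["terms"]),
    )


def _default_scan_k(config: PipelineConfig, landscape_ids: list[str]) -> dict[str, int]:
    if config.scan_k is not None:
        return dict(config.scan_k)
    if config.sim is not None:
        return dict(zip(landscape_ids, config.sim.n_clusters))
    return {lid: 3 for lid in landscape_ids}


def run_landscape(
    land: Landscape, config: PipelineConfig, k: int, seed
) -> dict:
    """Per-landscape stage: pruning, filtering, scans, consensus, assignment."""
    env_pruned, dropped_vars = prune_correlated_env(land.environment, config.r_max)
    filtered, filter_report = filter_genotypes(land.genotypes, config.thresholds)
    imputed = impute_missing(filtered, config.impute_strategy)
    locus_ids = list(imputed.locus_ids)
    env_ind = land.env_per_individual(env_pruned.columns)

    seed = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_axis, s_scan = seed.spawn(2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rda_model = fit_rda(imputed.dosage, env_ind)
        permutation_axis_test(
            rda_model, n_perm=config.n_perm, seed=s_axis, alpha=config.axis_alpha
        )
        rda_idx = rda_outlier_loci(rda_model, k_sd=config.rda_outlier_sd)
    rda_set = [locus_ids[j] for j in rda_idx]

    scan_cfg = ScanConfig(
        k=k, q_threshold=config.q_threshold, fdr_method=config.fdr_method,
        seed=int(np.random.default_rng(s_scan).integers(2**31 - 1)),
    )
    lfmm_res = lfmm_scan(imputed.dosage, env_ind, scan_cfg, locus_ids=locus_ids)
    pca_res = pcadapt_scan(imputed.dosage, scan_cfg, locus_ids=locus_ids)

    consensus, venn = consensus_candidates(
        rda_set, lfmm_res.selected, pca_res.selected,
        min_methods=config.min_methods, landscape_id=land.landscape_id,
    )
    if consensus.loci:
        sub = imputed.subset_loci(np.asarray(consensus.loci, dtype=object))
        consensus.assignments = assign_top_variable(consensus.loci, sub.dosage, env_ind)
    else:
        consensus.assignments = pd.DataFrame(columns=["locus_id", "variable", "r", "tie"])

    neutral = build_neutral_set(locus_ids, rda_set, lfmm_res.selected, pca_res.selected)
    return {
        "landscape_id": land.landscape_id,
        "env_pruned": env_pruned,
        "dropped_variables": dropped_vars,
        "filtered": filtered,
        "imputed": imputed,
        "filter_report": filter_report,
        "rda_model": rda_model,
        "method_sets": {"rda": rda_set, "lfmm": lfmm_res.selected, "pcadapt": pca_res.selected},
        "scan_results": {"lfmm": lfmm_res, "pcadapt": pca_res},
        "consensus": consensus,
        "venn": venn,
        "neutral": neutral,
        "gif": {"lfmm": lfmm_res.gif, "pcadapt": pca_res.gif},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study-level analysis; returns (and optionally writes) the bundle."""
    stage = "load"
    try:
        study = load_study(config)
        lids = study.landscape_ids
        scan_k = _default_scan_k(config, lids)
        ss = np.random.SeedSequence(config.seed)
        s_l1, s_l2, s_tests = ss.spawn(3)

        stage = "landscape-scans"
        per_land = {
            lid: run_landscape(study.landscapes[lid], config, scan_k[lid], s)
            for lid, s in zip(lids, (s_l1, s_l2))
        }

        stage = "environment-pca"
        env_all = pd.concat(
            [study.landscapes[lid].environment for lid in lids], axis=0
        )
        env_pca = environment_pca(env_all)

        stage = "repeatability-tests"
        imp_landscapes = {
            lid: Landscape(
                lid,
                study.landscapes[lid].samples,
                study.landscapes[lid].environment,
                per_land[lid]["imputed"],
            )
            for lid in lids
        }
        tests14 = repeated_selection_tests(
            imp_landscapes,
            {lid: per_land[lid]["consensus"].loci for lid in lids},
            {lid: per_land[lid]["neutral"] for lid in lids},
            {lid: list(per_land[lid]["env_pruned"].columns) for lid in lids},
            seed=s_tests,
            n_perm=config.n_perm,
        )

        stage = "variable-overlap"
        universe = sorted(
            set(per_land[lids[0]]["imputed"].locus_ids)
            & set(per_land[lids[1]]["imputed"].locus_ids)
        )
        overlap = variable_overlap_test(
            per_land[lids[0]]["consensus"].assignments,
            per_land[lids[1]]["consensus"].assignments,
            universe,
        )

        stage = "annotation"
        ann = AnnotationMap(annotation=study.annotation, terms=study.terms)
        genes = {}
        unmapped = {}
        for lid in lids:
            genes[lid], unmapped[lid] = map_candidates_to_genes(
                per_land[lid]["consensus"].loci, ann
            )
        shared, gene_counts = shared_gene_set(
            genes[lids[0]]["gene"], genes[lids[1]]["gene"]
        )

        stage = "enrichment"
        background = sorted(ann.background_genes())
        ora = over_representation(shared, background, ann, config.ora_q_threshold)
        a_s_genes = enriched_genes(ora) if len(ora) else []

        stage = "c-hyper"
        g0 = gene_counts["n_L1"] + gene_counts["n_L2"] - gene_counts["n_shared"]
        repeat_report = None
        if g0 >= 2 and 0 < gene_counts["n_shared"] < g0:
            inputs = RepeatabilityInputs(
                g0=g0,
                a_x=gene_counts["n_shared"],
                a_y=gene_counts["n_shared"],
                a_s=len(a_s_genes),
            )
            repeat_report = repeatability_report(inputs)

        stage = "shared-gene-gea"
        gea_tables = {}
        for lid in lids:
            freqs = site_allele_freq(
                per_land[lid]["filtered"], study.landscapes[lid].samples
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gea_tables[lid] = shared_gene_gea_table(
                    shared, freqs, per_land[lid]["env_pruned"], ann
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    bundle = {
        "config": config.effective(),
        "landscapes": per_land,
        "environment_pca": env_pca,
        "tests14": tests14,
        "variable_overlap": overlap,
        "genes": genes,
        "unmapped": unmapped,
        "gene_counts": gene_counts,
        "shared_genes": shared,
        "enrichment": ora,
        "enriched_genes": a_s_genes,
        "repeatability": repeat_report,
        "shared_gene_gea": gea_tables,
        "version": __version__,
    }
    if config.outdir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for lid, res in bundle["landscapes"].items():
        pd.DataFrame(
            [res["filter_report"].as_dict()]
        ).to_csv(out / f"{lid}.filter_report.tsv", sep="\t", index=False)
        for method, sr in res["scan_results"].items():
            sr.table.to_csv(out / f"{lid}.{method}.tsv", sep="\t", index=False)
        rda_tab = pd.DataFrame(
            res["rda_model"].loadings_,
            index=res["imputed"].locus_ids,
            columns=[f"RDA{a + 1}" for a in range(res["rda_model"].n_axes_)],
        )
        rda_tab.to_csv(out / f"{lid}.rda_loadings.tsv", sep="\t")
        pd.DataFrame(
            {
                "axis": np.arange(res["rda_model"].n_axes_) + 1,
                "eigenvalue": res["rda_model"].eigenvalues_,
                "p": res["rda_model"].axis_pvalues_,
            }
        ).to_csv(out / f"{lid}.rda_axes.tsv", sep="\t", index=False)
        cons = res["consensus"]
        prov = pd.DataFrame(
            {
                "locus_id": cons.loci,
                "methods": ["+".join(cons.provenance[l]) for l in cons.loci],
            }
        )
        prov.merge(cons.assignments, on="locus_id", how="left").to_csv(
            out / f"{lid}.candidates.tsv", sep="\t", index=False
        )
        pd.Series(res["venn"]).to_csv(out / f"{lid}.venn.tsv", sep="\t", header=False)
        pd.Series(res["neutral"]).to_csv(
            out / f"{lid}.neutral.tsv", sep="\t", index=False, header=False
        )
    bundle["tests14"].to_csv(out / "tests14.tsv", sep="\t", index=False)
    bundle["variable_overlap"].to_csv(out / "variable_overlap.tsv", sep="\t", index=False)
    bundle["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for lid, tab in bundle["shared_gene_gea"].items():
        tab.to_csv(out / f"{lid}.shared_gene_gea.tsv", sep="\t", index=False)
    rep = bundle["repeatability"]
    report = {
        "gene_counts": bundle["gene_counts"],
        "enriched_genes": bundle["enriched_genes"],
        "repeatability": None
        if rep is None
        else {
            "g0": rep.inputs.g0,
            "a_x": rep.inputs.a_x,
            "a_y": rep.inputs.a_y,
            "a_s": rep.inputs.a_s,
            "expected": rep.expected_overlap,
            "sd": rep.sd_overlap,
            "c_hyper": rep.c_hyper,
            "p": rep.p_value,
        },
    }
    (out / "repeatability.json").write_text(json.dumps(report, indent=2))
    log = {
        "seed": bundle["config"]["seed"],
        "version": bundle["version"],
        "config": bundle["config"],
        "gif": {lid: res["gif"] for lid, res in bundle["landscapes"].items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
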