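"""Reading and writing the study's standard file formats.

A study on disk is, per landscape, a VCFv4.2 genotype file (GT, optional
DP/GQ), a samples CSV (individual_id, site_id, landscape_id) and an
environment CSV (site x variables); study-level, an annotation CSV
(locus_id, contig, gene), a terms CSV (term, category, gene) and — for
synthetic studies — truth CSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GenotypeMatrix, Landscape, Study

__all__ = ["write_vcf", "read_vcf", "write_study", "read_study"]


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a dosage matrix as an uncompressed VCFv4.2 (GT, optional DP/GQ)."""
    path = Path(path)
    has_dp, has_gq = geno.depth is not None, geno.qual is not None
    fmt_fields = ["GT"] + (["DP"] if has_dp else []) + (["GQ"] if has_gq else [])
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for contig in pd.unique(geno.loci["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        cols = "\t".join(geno.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, locus in enumerate(geno.loci.itertuples(index=False)):
            calls = []
            for i in range(geno.n_individuals):
                d = geno.dosage[i, j]
                parts = ["./." if np.isnan(d) else gt_code[d]]
                if has_dp:
                    parts.append(str(int(geno.depth[i, j])))
                if has_gq:
                    parts.append(str(int(geno.qual[i, j])))
                calls.append(":".join(parts))
            fh.write(
                f"{locus.contig}\t{locus.pos}\t{locus.locus_id}\t{locus.ref}\t{locus.alt}"
                f"\t.\tPASS\t.\t{':'.join(fmt_fields)}\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a GenotypeMatrix; non-biallelic records are dropped.

    Returns the matrix and the count of dropped non-biallelic records.
    Locus ids are ``contig:position`` (1-based).
    """
    vcf = VCF(str(path), gts012=True)
    samples = pd.Index(vcf.samples)
    rows, dosage_cols, depth_cols, qual_cols = [], [], [], []
    n_dropped = 0
    any_dp = any_gq = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            continue
        rows.append((f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(float)  # 0/1/2 dosage, 3 = missing under gts012
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        if dp is not None:
            any_dp = True
            depth_cols.append(np.asarray(dp, dtype=float).ravel())
        else:
            depth_cols.append(np.full(len(samples), np.nan))
        if gq is not None:
            any_gq = True
            qual_cols.append(np.asarray(gq, dtype=float).ravel())
        else:
            qual_cols.append(np.full(len(samples), np.nan))
    loci = pd.DataFrame(rows, columns=["locus_id", "contig", "pos", "ref", "alt"])
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    gm = GenotypeMatrix(
        dosage=dosage,
        loci=loci,
        samples=samples,
        depth=np.column_stack(depth_cols) if any_dp else None,
        qual=np.column_stack(qual_cols) if any_gq else None,
    )
    return gm, n_dropped


def write_study(study: Study, outdir) -> None:
    """Serialize a Study: per-landscape VCF + CSVs, plus annotation/terms/truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lid, land in study.landscapes.items():
        write_vcf(land.genotypes, outdir / f"{lid}.vcf")
        land.samples.to_csv(outdir / f"{lid}.samples.csv", index=False)
        land.environment.to_csv(outdir / f"{lid}.env.csv")
    study.annotation.to_csv(outdir / "annotation.csv", index=False)
    study.terms.to_csv(outdir / "terms.csv", index=False)
    if study.truth is not None:
        study.truth.loci.to_csv(outdir / "truth.loci.csv", index=False)
        study.truth.genes.to_csv(outdir / "truth.genes.csv", index=False)
        study.truth.terms.to_csv(outdir / "truth.terms.csv", index=False)


def read_landscape(lid: str, vcf_path, samples_path, env_path) -> Landscape:
    gm, _ = read_vcf(vcf_path)
    samples = pd.read_csv(samples_path)
    env = pd.read_csv(env_path, index_col=0)
    vcf_ids = set(gm.samples)
    table_ids = set(samples["individual_id"])
    if vcf_ids != table_ids:
        only_vcf = sorted(vcf_ids - table_ids)
        only_table = sorted(table_ids - vcf_ids)
        raise ValueError(
            f"sample mismatch for {lid}: in VCF only {only_vcf}; in table only {only_table}"
        )
    samples = samples.set_index("individual_id").loc[list(gm.samples)].reset_index()
    return Landscape(lid, samples, env, gm)


def read_study(indir, landscape_ids=("L1", "L2")) -> Study:
    indir = Path(indir)
    landscapes = {
        lid: read_landscape(
            lid, indir / f"{lid}.vcf", indir / f"{lid}.samples.csv", indir / f"{lid}.env.csv"
        )
        for lid in landscape_ids
    }
    return Study(
        landscapes=landscapes,
        annotation=pd.read_csv(indir / "annotation.csv"),
        terms=pd.read_csv(indir / "terms.csv"),
    )
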