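"""Core in-memory containers shared across the pipeline.

The pipeline operates on a :class:`Study` — a pair of independently sampled
landscapes, each with its own sample table, site-level environment table and
genotype matrix — plus study-level annotation (locus → contig → gene) and
functional term membership tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Landscape",
    "Study",
    "FilterThresholds",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, dosage-coded.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing
    calls; dosage counts the alternate allele.  ``loci`` carries per-locus
    metadata indexed 0..L-1 with columns ``locus_id, contig, pos, ref, alt``.
    ``depth`` and ``qual`` are optional per-genotype arrays (same shape as
    ``dosage``) used by the quality-masking filter step.
    """

    dosage: np.ndarray
    loci: pd.DataFrame
    samples: pd.Index
    depth: Optional[np.ndarray] = None
    qual: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        n, m = self.dosage.shape
        if len(self.loci) != m:
            raise ValueError(f"loci table has {len(self.loci)} rows, dosage has {m} columns")
        self.samples = pd.Index(self.samples)
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} samples for {n} dosage rows")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def locus_ids(self) -> pd.Index:
        return pd.Index(self.loci["locus_id"])

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset_loci(self, keep) -> "GenotypeMatrix":
        """Return a copy restricted to loci selected by boolean mask or locus ids."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = pd.Index(self.loci["locus_id"]).get_indexer(keep)
            if (pos < 0).any():
                missing = list(np.asarray(keep)[pos < 0][:5])
                raise KeyError(f"locus ids not present: {missing}")
            idx = pos
        return GenotypeMatrix(
            dosage=self.dosage[:, idx].copy(),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            qual=None if self.qual is None else self.qual[:, idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage.copy(),
            loci=self.loci.copy(),
            samples=self.samples.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            qual=None if self.qual is None else self.qual.copy(),
        )


@dataclass
class Landscape:
    """One replicate landscape: samples, site environment, genotypes."""

    landscape_id: str
    samples: pd.DataFrame  # columns: individual_id, site_id, landscape_id
    environment: pd.DataFrame  # index: site_id, columns: variables
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        required = {"individual_id", "site_id", "landscape_id"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample table needs columns {sorted(required)}")
        if self.samples["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in sample table")
        unknown = set(self.samples["site_id"]) - set(self.environment.index)
        if unknown:
            raise ValueError(f"samples reference sites absent from environment: {sorted(unknown)}")
        order = pd.Index(self.samples["individual_id"])
        if not order.equals(self.genotypes.samples):
            raise ValueError("genotype sample order must match sample table order")

    def env_per_individual(self, variables=None) -> pd.DataFrame:
        """Broadcast site-level environment to one row per individual."""
        env = self.environment if variables is None else self.environment[list(variables)]
        rows = env.loc[self.samples["site_id"].to_numpy()]
        rows.index = pd.Index(self.samples["individual_id"])
        return rows


@dataclass
class Study:
    """Two-landscape study bundle with annotation and term tables."""

    landscapes: dict[str, Landscape]
    annotation: pd.DataFrame  # columns: locus_id, contig, gene
    terms: pd.DataFrame  # columns: term, category, gene
    truth: Optional["object"] = None  # SyntheticTruth for simulated studies

    def __post_init__(self) -> None:
        if len(self.landscapes) != 2:
            raise ValueError("a Study holds exactly two landscapes")
        ids = [
            set(l.samples["individual_id"]) for l in self.landscapes.values()
        ]
        if ids[0] & ids[1]:
            raise ValueError("landscapes must have disjoint individuals")

    @property
    def landscape_ids(self) -> list[str]:
        return list(self.landscapes)


@dataclass(frozen=True)
class FilterThresholds:
    """Post-calling genotype quality thresholds.

    Defaults follow common RADseq practice: genotype calls below 10x depth or
    GQ 20 are masked, loci with >20% missing calls, minor-allele frequency
    below 0.05 or Hardy-Weinberg exact p below 1e-4 are removed.
    """

    min_depth: int = 10
    min_genotype_quality: int = 20
    max_missing: float = 0.20
    maf_min: float = 0.05
    hwe_alpha: float = 1e-4
    #: remove loci *deviating* from HWE (p < alpha).  The inverse direction
    #: (p > alpha) is exposed for strict replication of alternative protocols.
    hwe_remove_deviating: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing", "maf_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_depth < 0 or self.min_genotype_quality < 0:
            raise ValueError("depth/quality thresholds must be >= 0")
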