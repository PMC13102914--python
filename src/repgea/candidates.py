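"""Consensus candidate calling and neutral/random comparison sets.

Candidate SNPs are those flagged by at least two of the three detection
methods (RDA loading outliers, LFMM, PCA-Mahalanobis); the neutral
comparison set removes the *union* of all methods' outliers, and
size-matched random sets are drawn from it without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CandidateSet",
    "consensus_candidates",
    "build_neutral_set",
    "sample_matched_random_sets",
]

METHODS = ("rda", "lfmm", "pcadapt")


@dataclass
class CandidateSet:
    """Consensus candidates with per-locus method provenance."""

    landscape_id: str
    loci: list[str]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)
    assignments: pd.DataFrame | None = None  # per-locus variable + signed r

    def __len__(self) -> int:
        return len(self.loci)


def consensus_candidates(
    rda_set, lfmm_set, pcadapt_set, min_methods: int = 2, landscape_id: str = ""
) -> tuple[CandidateSet, dict[str, int]]:
    """Loci detected by at least ``min_methods`` of the three methods.

    Also returns the seven Venn region counts keyed by the subset of methods
    (e.g. ``"rda+lfmm"`` = in RDA and LFMM but not PCAdapt).
    """
    sets = {"rda": set(rda_set), "lfmm": set(lfmm_set), "pcadapt": set(pcadapt_set)}
    universe = sets["rda"] | sets["lfmm"] | sets["pcadapt"]
    venn: dict[str, int] = {}
    membership: dict[str, tuple[str, ...]] = {}
    for locus in universe:
        members = tuple(m for m in METHODS if locus in sets[m])
        membership[locus] = members
        key = "+".join(members)
        venn[key] = venn.get(key, 0) + 1
    for r in range(1, 4):
        from itertools import combinations

        for combo in combinations(METHODS, r):
            venn.setdefault("+".join(combo), 0)
    loci = sorted(l for l, m in membership.items() if len(m) >= min_methods)
    cs = CandidateSet(
        landscape_id=landscape_id,
        loci=loci,
        provenance={l: membership[l] for l in loci},
    )
    return cs, venn


def build_neutral_set(all_loci, rda_set, lfmm_set, pcadapt_set) -> list[str]:
    """All loci minus the union of the three methods' outlier sets."""
    union = set(rda_set) | set(lfmm_set) | set(pcadapt_set)
    neutral = [l for l in all_loci if l not in union]
    if not neutral:
        raise ValueError("neutral set is empty: methods flagged every locus")
    return neutral


def sample_matched_random_sets(neutral_set, sizes, seed) -> list[list[str]]:
    """Draw size-matched random sets from the neutral loci, without replacement.

    Draws are independent across requested sizes and reproducible from the
    seed.
    """
    neutral = list(neutral_set)
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        if size > len(neutral):
            raise ValueError(f"requested {size} loci from a neutral set of {len(neutral)}")
        pick = rng.choice(len(neutral), size=size, replace=False)
        out.append([neutral[i] for i in sorted(pick)])
    return out
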