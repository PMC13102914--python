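"""Cross-landscape repeatability statistics.

The central question: do the two independently analyzed landscapes use the
same genes to respond to similar selection pressures?  Three layers of
evidence are computed here:

* the 14-test variance-explained design — RDAs of candidate, neutral and
  size-matched random SNP sets against each landscape's environment,
  including crossed tests of one landscape's loci on the other's data;
* hypergeometric overlap tests of candidate loci assigned to the same
  environmental variable in both landscapes;
* the C_hyper repeated-adaptation score: the observed gene overlap
  standardized by its hypergeometric mean and SD,
  ``C_hyper = (a_s - a_x a_y / g0) / sd``, with
  ``sd = sqrt((a_x a_y / g0)(1 - a_x/g0)((g0 - a_y)/(g0 - 1)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rda import rda_variance_test

__all__ = [
    "RepeatabilityInputs",
    "RepeatabilityReport",
    "hypergeometric_moments",
    "c_hyper_score",
    "c_hyper_pvalue",
    "repeatability_report",
    "variable_overlap_test",
    "repeated_selection_tests",
]


@dataclass(frozen=True)
class RepeatabilityInputs:
    """Counts feeding the C-score.

    g0: universe gene count; a_x, a_y: genes contributing to selection in
    each landscape; a_s: observed overlap of contributing genes.
    """

    g0: int
    a_x: int
    a_y: int
    a_s: int

    def __post_init__(self) -> None:
        if self.g0 < 2:
            raise ValueError("g0 must be >= 2")
        if not (0 <= self.a_x <= self.g0 and 0 <= self.a_y <= self.g0):
            raise ValueError("a_x and a_y must lie in [0, g0]")
        if not 0 <= self.a_s <= min(self.a_x, self.a_y):
            raise ValueError("a_s must lie in [0, min(a_x, a_y)]")


@dataclass(frozen=True)
class RepeatabilityReport:
    c_hyper: float
    expected_overlap: float
    sd_overlap: float
    p_value: float
    inputs: RepeatabilityInputs


def hypergeometric_moments(g0: int, a_x: int, a_y: int) -> tuple[float, float]:
    """Mean and SD of the gene overlap under the hypergeometric null.

    Drawing ``a_y`` genes from a universe of ``g0`` of which ``a_x`` are
    "contributing", the overlap X is hypergeometric with
    E[X] = a_x a_y / g0 and
    SD[X] = sqrt((a_x a_y / g0)(1 - a_x / g0)((g0 - a_y)/(g0 - 1))).
    """
    if g0 <= 1:
        raise ValueError("g0 must be > 1")
    expected = a_x * a_y / g0
    sd = math.sqrt(expected * (1.0 - a_x / g0) * ((g0 - a_y) / (g0 - 1)))
    return expected, sd


def c_hyper_score(inputs: RepeatabilityInputs) -> float:
    """Standardized repeated-adaptation score (positive when overlap exceeds chance)."""
    expected, sd = hypergeometric_moments(inputs.g0, inputs.a_x, inputs.a_y)
    if sd == 0:
        raise ValueError("degenerate inputs: overlap SD is zero")
    return (inputs.a_s - expected) / sd


def c_hyper_pvalue(inputs: RepeatabilityInputs) -> float:
    """Exact upper-tail P(X >= a_s) under hypergeometric(g0, a_x, a_y)."""
    return float(stats.hypergeom.sf(inputs.a_s - 1, inputs.g0, inputs.a_x, inputs.a_y))


def repeatability_report(inputs: RepeatabilityInputs) -> RepeatabilityReport:
    expected, sd = hypergeometric_moments(inputs.g0, inputs.a_x, inputs.a_y)
    return RepeatabilityReport(
        c_hyper=c_hyper_score(inputs),
        expected_overlap=expected,
        sd_overlap=sd,
        p_value=c_hyper_pvalue(inputs),
        inputs=inputs,
    )


def variable_overlap_test(
    assignments_L1: pd.DataFrame, assignments_L2: pd.DataFrame, universe
) -> pd.DataFrame:
    """Hypergeometric tests of shared variable-specific candidate loci.

    ``assignments_*`` map candidate loci to their top environmental variable
    (columns ``locus_id``, ``variable``); ``universe`` is the locus set
    genotyped and filtered in BOTH landscapes.  For each variable v, with
    N = |universe|, K = L1 candidates assigned v, n = L2 candidates assigned
    v and k their shared loci, the upper-tail p is P(X >= k) under
    hypergeometric(N, K, n).  A pooled row applies the same construction to
    the full candidate sets and their same-variable overlap.
    """
    universe = set(universe)
    N = len(universe)
    a1 = assignments_L1[assignments_L1["locus_id"].isin(universe)]
    a2 = assignments_L2[assignments_L2["locus_id"].isin(universe)]
    m1 = dict(zip(a1["locus_id"], a1["variable"]))
    m2 = dict(zip(a2["locus_id"], a2["variable"]))
    variables = sorted(
        {v for v in list(m1.values()) + list(m2.values()) if v is not None}
    )
    rows = []
    for v in variables:
        s1 = {l for l, vv in m1.items() if vv == v}
        s2 = {l for l, vv in m2.items() if vv == v}
        k = len(s1 & s2)
        p = float(stats.hypergeom.sf(k - 1, N, len(s1), len(s2)))
        rows.append((v, N, len(s1), len(s2), k, p))
    pooled_k = sum(
        1 for l in set(m1) & set(m2) if m1[l] is not None and m1[l] == m2[l]
    )
    rows.append((
        "pooled", N, len(m1), len(m2), pooled_k,
        float(stats.hypergeom.sf(pooled_k - 1, N, len(m1), len(m2))),
    ))
    return pd.DataFrame(rows, columns=["variable", "N", "K_L1", "n_L2", "k_shared", "p"])


TEST_LABELS = tuple("abcdefghijklmn")


def _extract(landscape, loci: list[str]):
    """Imputed dosage of a landscape at the requested loci; drops absent ones."""
    present = [l for l in loci if l in set(landscape.genotypes.locus_ids)]
    gm = landscape.genotypes.subset_loci(np.asarray(present, dtype=object))
    return gm.dosage, len(loci) - len(present)


def repeated_selection_tests(
    landscapes: dict,
    candidate_sets: dict,
    neutral_sets: dict,
    env_variables: dict,
    seed,
    n_perm: int = 999,
) -> pd.DataFrame:
    """The 14-test cross-landscape variance-explained design.

    ``landscapes`` maps id -> Landscape whose genotype matrices are filtered
    and imputed; ``candidate_sets``/``neutral_sets`` map id -> locus-id
    lists; ``env_variables`` maps id -> the pruned variable names for that
    landscape.  Rows (labels a-n):

    a, b  candidates of each landscape on their own environment;
    c, d  the same candidate loci evaluated in the *other* landscape
          (its individuals and environment; loci missing there are dropped
          and counted);
    e, f  the full neutral sets on their own environment;
    g-j   size-matched random-neutral sets (both candidate sizes x both
          landscapes) on their own environment;
    k-n   the random sets crossed to the other landscape.

    Each row reports R^2, adjusted R^2 and the global permutation p from
    :func:`repgea.rda.rda_variance_test`.
    """
    (l1, l2) = list(landscapes)
    sizes = {l1: len(candidate_sets[l1]), l2: len(candidate_sets[l2])}
    rng_master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    s_rand1, s_rand2, *s_tests = rng_master.spawn(2 + 14)

    from .candidates import sample_matched_random_sets

    rand = {
        l1: sample_matched_random_sets(neutral_sets[l1], [sizes[l1], sizes[l2]], s_rand1),
        l2: sample_matched_random_sets(neutral_sets[l2], [sizes[l1], sizes[l2]], s_rand2),
    }

    def set_name(kind: str, loci: list[str], origin: str) -> str:
        prefix = {"candidate": "Set", "neutral": "SetN", "random": "SetRN"}[kind]
        return f"{prefix}-{len(loci)}-{origin}"

    plan = [
        # label, kind, loci-origin landscape, loci, test landscape
        ("a", "candidate", l1, candidate_sets[l1], l1),
        ("b", "candidate", l2, candidate_sets[l2], l2),
        ("c", "candidate", l1, candidate_sets[l1], l2),
        ("d", "candidate", l2, candidate_sets[l2], l1),
        ("e", "neutral", l1, neutral_sets[l1], l1),
        ("f", "neutral", l2, neutral_sets[l2], l2),
        ("g", "random", l1, rand[l1][0], l1),
        ("h", "random", l1, rand[l1][1], l1),
        ("i", "random", l2, rand[l2][0], l2),
        ("j", "random", l2, rand[l2][1], l2),
        ("k", "random", l1, rand[l1][0], l2),
        ("l", "random", l1, rand[l1][1], l2),
        ("m", "random", l2, rand[l2][0], l1),
        ("n", "random", l2, rand[l2][1], l1),
    ]
    rows = []
    for (label, kind, origin, loci, target), s_test in zip(plan, s_tests):
        land = landscapes[target]
        Y, n_dropped = _extract(land, list(loci))
        X = land.env_per_individual(env_variables[target])
        res = rda_variance_test(Y, X, n_perm=n_perm, seed=s_test)
        rows.append({
            "test": label,
            "snp_set": set_name(kind, list(loci), origin),
            "set_kind": kind,
            "origin_landscape": origin,
            "env_landscape": target,
            "n_loci": Y.shape[1],
            "n_dropped": n_dropped,
            "R2": res["R2"],
            "adjusted_R2": res["adjusted_R2"],
            "p_global": res["p_global"],
        })
    return pd.DataFrame(rows)
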