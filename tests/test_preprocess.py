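"""Environment pruning, PCA, HWE exact test and the genotype filter cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from repgea.datatypes import FilterThresholds, GenotypeMatrix
from repgea.preprocess import (
    environment_pca,
    filter_genotypes,
    hwe_exact_test,
    impute_missing,
    prune_correlated_env,
    site_allele_freq,
)

from conftest import exact_correlation_table


def corr_from(names_pairs: dict, names: list) -> np.ndarray:
    p = len(names)
    c = np.eye(p)
    for (a, b), r in names_pairs.items():
        i, j = names.index(a), names.index(b)
        c[i, j] = c[j, i] = r
    return c


class TestPruneCorrelatedEnv:
    def test_perfectly_correlated_pair_loses_one_member(self):
        env = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0]})
        env["B"] = 2 * env["A"] + 1
        pruned, dropped = prune_correlated_env(env)
        assert len(dropped) == 1 and pruned.shape[1] == 1

    def test_hub_variable_dropped_others_kept(self):
        names = ["A", "B", "C"]
        corr = corr_from({("A", "B"): 0.95, ("A", "C"): 0.85, ("B", "C"): 0.65}, names)
        env = exact_correlation_table(corr, names, n_rows=30, seed=4)
        pruned, dropped = prune_correlated_env(env, r_max=0.8)
        assert dropped == ["A"]
        assert set(pruned.columns) == {"B", "C"}

    def test_field_scenario_removes_ph_and_no_leaving_eight(self):
        """A pH/NO-centered correlated block loses exactly those two of ten."""
        names = ["AT", "EVA", "K", "NO", "Na", "OA", "RH", "SR", "WT", "pH"]
        # one runoff factor loads the water-chemistry block; pH is the hub
        load = {"pH": 0.97, "NO": 0.928, "K": 0.876, "Na": 0.874}
        lam = np.array([[load.get(n, 0.0)] for n in names])
        corr = lam @ lam.T
        np.fill_diagonal(corr, 1.0)
        env = exact_correlation_table(corr, names, n_rows=20, seed=8)
        pruned, dropped = prune_correlated_env(env, r_max=0.8)
        assert sorted(dropped) == ["NO", "pH"]
        assert pruned.shape[1] == 8

    def test_zero_variance_variable_dropped_first_with_warning(self):
        env = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0], "C": [3.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            pruned, dropped = prune_correlated_env(env)
        assert dropped[0] == "B"

    @pytest.mark.parametrize("seed", range(5))
    def test_output_never_contains_a_pair_at_or_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((15, 3))
        mix = base @ rng.standard_normal((3, 7)) + 0.3 * rng.standard_normal((15, 7))
        env = pd.DataFrame(mix, columns=list("ABCDEFG"))
        pruned, _ = prune_correlated_env(env, r_max=0.8)
        corr = pruned.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.8


class TestEnvironmentPCA:
    def test_duplicated_landscapes_have_coincident_centroids(self):
        rng = np.random.default_rng(0)
        block = pd.DataFrame(rng.standard_normal((6, 4)), columns=list("WXYZ"))
        both = pd.concat([block, block], axis=0, ignore_index=True)
        res = environment_pca(both)
        c1 = res["scores"].iloc[:6].mean()
        c2 = res["scores"].iloc[6:].mean()
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_single_varying_variable_owns_all_variance(self):
        env = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": 1.0, "C": 2.0})
        res = environment_pca(env)
        assert res["explained"].iloc[0] == pytest.approx(1.0)

    def test_reconstruction_from_all_components_is_exact(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame(rng.standard_normal((8, 8)))
        res = environment_pca(env)
        Z = (env - env.mean()) / env.std(ddof=0)
        recon = res["scores"].to_numpy() @ res["loadings"].to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        env = pd.DataFrame(rng.standard_normal((10, 5)))
        assert environment_pca(env)["explained"].sum() == pytest.approx(1.0)


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-arithmetic enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = n_Aa + 2 * n_AA
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    denom = math.comb(2 * n, rare)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h] = (
            math.comb(n, hom_r) * math.comb(n - hom_r, h) * 2**h
        ) / denom
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return sum(v / total for v in probs.values() if v / total <= obs * (1 + 1e-12))


class TestHweExactTest:
    def test_perfect_hwe_counts_are_modal(self):
        assert hwe_exact_test(25, 50, 25) >= 0.5

    def test_total_heterozygote_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    def test_monomorphic_locus_returns_one(self):
        assert hwe_exact_test(0, 0, 10) == 1.0
        assert hwe_exact_test(7, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(3, 5, 2), (10, 2, 10), (1, 14, 1), (0, 6, 4), (12, 12, 12), (20, 1, 5)]
    )
    def test_matches_exact_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)


def toy_matrix():
    """10 loci engineered with one violation per filter step.

    locus 0: depth-masked genotypes; locus 1: >20% missing; locus 2: MAF 0;
    locus 3: gross heterozygote deficit (HWE); the rest are clean.
    """
    rng = np.random.default_rng(42)
    n = 60
    dosage = rng.binomial(2, 0.5, size=(n, 10)).astype(float)
    depth = np.full((n, 10), 30.0)
    depth[:10, 0] = 5.0  # below minDP -> masked (16.7% missing, still kept)
    dosage[: int(n * 0.21) + 1, 1] = np.nan
    dosage[:, 2] = 0.0
    dosage[:, 3] = np.repeat([0.0, 2.0], n // 2)
    loci = pd.DataFrame(
        {
            "locus_id": [f"c{j}:100" for j in range(10)],
            "contig": [f"c{j}" for j in range(10)],
            "pos": 100, "ref": "A", "alt": "T",
        }
    )
    return GenotypeMatrix(dosage, loci, pd.Index([f"I{i}" for i in range(n)]), depth=depth)


class TestFilterGenotypes:
    def test_each_step_removes_its_constructed_violation(self):
        gm = toy_matrix()
        out, report = filter_genotypes(gm, FilterThresholds())
        assert report.genotypes_masked == 10
        assert report.removed_missing == 1
        assert report.removed_maf == 1
        assert report.removed_hwe == 1
        assert out.n_loci == 7
        assert "c1:100" not in set(out.locus_ids)
        assert "c2:100" not in set(out.locus_ids)
        assert "c3:100" not in set(out.locus_ids)

    def test_missingness_boundary_is_strict(self):
        n = 100
        dosage = np.ones((n, 2))
        dosage[1:, 0] = np.tile([0, 1, 2], 33)
        dosage[1:, 1] = np.tile([0, 1, 2], 33)
        dosage[:20, 0] = np.nan  # exactly 20%: kept
        dosage[:21, 1] = np.nan  # 21%: removed
        loci = pd.DataFrame(
            {"locus_id": ["a:1", "b:1"], "contig": ["a", "b"], "pos": 1, "ref": "A", "alt": "T"}
        )
        gm = GenotypeMatrix(dosage, loci, pd.Index([f"I{i}" for i in range(n)]))
        out, report = filter_genotypes(gm, FilterThresholds(hwe_alpha=0.0))
        assert report.removed_missing == 1
        assert list(out.locus_ids) == ["a:1"]

    def test_filtering_is_idempotent(self):
        gm = toy_matrix()
        once, _ = filter_genotypes(gm)
        twice, rep2 = filter_genotypes(once)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert rep2.removed_missing == rep2.removed_maf == rep2.removed_hwe == 0

    def test_emptying_step_is_named(self):
        dosage = np.zeros((10, 2))
        loci = pd.DataFrame(
            {"locus_id": ["a:1", "b:1"], "contig": ["a", "b"], "pos": 1, "ref": "A", "alt": "T"}
        )
        gm = GenotypeMatrix(dosage, loci, pd.Index([f"I{i}" for i in range(10)]))
        with pytest.raises(ValueError, match="MAF"):
            filter_genotypes(gm)


class TestImputeAndSiteFreq:
    def _gm(self, col):
        dosage = np.asarray(col, dtype=float).reshape(-1, 1)
        loci = pd.DataFrame(
            {"locus_id": ["a:1"], "contig": ["a"], "pos": 1, "ref": "A", "alt": "T"}
        )
        return GenotypeMatrix(dosage, loci, pd.Index([f"I{i}" for i in range(len(col))]))

    def test_complete_matrix_unchanged(self):
        gm = self._gm([0, 1, 2, 2])
        np.testing.assert_array_equal(impute_missing(gm).dosage, gm.dosage)

    def test_modal_imputation(self):
        gm = self._gm([0, 0, 2, np.nan])
        assert impute_missing(gm, "most_frequent").dosage[3, 0] == 0.0

    def test_mean_imputation(self):
        gm = self._gm([0, 1, 2, np.nan])
        assert impute_missing(gm, "mean").dosage[3, 0] == pytest.approx(1.0)

    def test_fully_missing_locus_is_an_error(self):
        gm = self._gm([np.nan, np.nan])
        with pytest.raises(ValueError, match="fully missing"):
            impute_missing(gm)

    def test_site_allele_frequencies(self):
        dosage = np.array(
            [[0.0], [0.0], [0.0], [2.0], [2.0], [0.0], [1.0], [2.0], [np.nan]]
        )
        loci = pd.DataFrame(
            {"locus_id": ["a:1"], "contig": ["a"], "pos": 1, "ref": "A", "alt": "T"}
        )
        samples = pd.DataFrame(
            {
                "individual_id": [f"I{i}" for i in range(9)],
                "site_id": ["s1"] * 3 + ["s2"] * 2 + ["s3"] * 4,
                "landscape_id": "L1",
            }
        )
        gm = GenotypeMatrix(dosage, loci, pd.Index(samples["individual_id"]))
        freq = site_allele_freq(gm, samples)
        assert freq.loc["s1"].iloc[0] == 0.0
        assert freq.loc["s2"].iloc[0] == 1.0
        assert freq.loc["s3"].iloc[0] == pytest.approx(0.5)
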