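"""The constrained-ordination engine and its permutation machinery."""

import shutil
import subprocess
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from repgea.rda import (
    RDA,
    assign_top_variable,
    fit_rda,
    permutation_axis_test,
    rda_outlier_loci,
    rda_variance_test,
)


def random_xy(seed=0, n=20, L=50, q=3):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, q)), rng.standard_normal((n, L))


class TestFitRda:
    def test_noiseless_linear_response_has_unit_r_squared(self):
        X, _ = random_xy(1)
        W = np.random.default_rng(2).standard_normal((3, 10))
        model = fit_rda(X @ W, X)
        assert model.r_squared_ == pytest.approx(1.0, abs=1e-10)
        assert model.residual_inertia_ == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_response_has_zero_r_squared(self):
        X, Y = random_xy(3)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        # residualize Y on X so the constrained projection vanishes
        Yo = Yc - Xc @ np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        model = fit_rda(Yo, X)
        assert model.r_squared_ == pytest.approx(0.0, abs=1e-10)

    def test_r_squared_matches_entrywise_hat_projection(self):
        X, Y = random_xy(4)
        model = fit_rda(Y, X)
        Xc = X - X.mean(axis=0)
        Xc = Xc / Xc.std(axis=0, ddof=1)
        H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
        Yc = Y - Y.mean(axis=0)
        fitted = H @ Yc
        assert model.r_squared_ == pytest.approx(
            float((fitted**2).sum() / (Yc**2).sum()), abs=1e-10
        )
        n, q = X.shape
        adj = 1 - (1 - model.r_squared_) * (n - 1) / (n - q - 1)
        assert model.adjusted_r_squared_ == pytest.approx(adj, abs=1e-10)

    def test_inertia_conservation(self):
        X, Y = random_xy(5)
        model = fit_rda(Y, X)
        assert model.eigenvalues_.sum() + model.residual_inertia_ == pytest.approx(
            model.total_inertia_, abs=1e-8
        )

    def test_invariant_to_locus_column_order(self):
        X, Y = random_xy(6)
        perm = np.random.default_rng(7).permutation(Y.shape[1])
        a = fit_rda(Y, X)
        b = fit_rda(Y[:, perm], X)
        np.testing.assert_allclose(a.eigenvalues_, b.eigenvalues_, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(a.loadings_[perm]), np.abs(b.loadings_), atol=1e-8
        )

    def test_collinear_predictor_dropped_with_warning(self):
        X, Y = random_xy(8)
        X2 = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            model = fit_rda(Y, X2)
        assert model.rank_ == 3

    def test_too_few_rows_rejected(self):
        X, Y = random_xy(9, n=4, q=3)
        with pytest.raises(ValueError, match="rank"):
            fit_rda(Y, X)


class TestPermutationAxisTest:
    def test_matches_naive_refit_oracle_on_first_axis(self):
        """Axis-1 p equals a re-fit-per-permutation oracle sharing the draws."""
        rng = np.random.default_rng(10)
        n, L = 15, 12
        signal = rng.standard_normal(n)
        X = np.column_stack([signal, rng.standard_normal(n)])
        Y = np.outer(signal, rng.standard_normal(L)) + 0.5 * rng.standard_normal((n, L))
        model = fit_rda(Y, X)
        B = 99
        p = permutation_axis_test(model, n_perm=B, seed=123)

        # oracle: full refit per permutation, same statistic definition
        draws = np.random.default_rng(123)
        Yc = Y - Y.mean(axis=0)
        base = fit_rda(Y, X)
        df_res = n - 1 - base.rank_
        f_obs = base.eigenvalues_[0] / (base.residual_inertia_ / df_res)
        count = 0
        for _ in range(B):
            perm = draws.permutation(n)
            m = fit_rda(Yc[np.argsort(perm)], X)  # row-permuted response
            f_b = m.eigenvalues_[0] / ((m.total_inertia_ - m.constrained_inertia_) / df_res)
            if f_b >= f_obs - 1e-12:
                count += 1
        assert p[0] == pytest.approx((count + 1) / (B + 1))
        assert p[0] <= 3 / (B + 1)  # strong planted signal: near-minimal p

    def test_null_rejection_rate_is_calibrated(self):
        hits = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((12, 2))
            Y = rng.standard_normal((12, 15))
            model = fit_rda(Y, X)
            p = permutation_axis_test(model, n_perm=99, seed=s)
            hits += p[0] <= 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_same_seed_gives_identical_pvalues(self):
        X, Y = random_xy(11)
        m1 = fit_rda(Y, X)
        m2 = fit_rda(Y, X)
        p1 = permutation_axis_test(m1, n_perm=49, seed=5)
        p2 = permutation_axis_test(m2, n_perm=49, seed=5)
        np.testing.assert_array_equal(p1, p2)


class TestOutlierLoci:
    def _model(self, loadings):
        return SimpleNamespace(loadings_=np.asarray(loadings, dtype=float))

    def test_degenerate_equal_loadings_yield_no_outliers(self):
        m = self._model(np.ones((50, 1)))
        assert rda_outlier_loci(m, significant_axes=[0]).size == 0

    def test_planted_five_sd_outlier_recovered(self):
        recovered = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            load = rng.standard_normal(1000)
            load[37] = load.mean() + 5 * load.std()
            out = rda_outlier_loci(self._model(load[:, None]), significant_axes=[0])
            recovered += 37 in out
        assert recovered >= 95

    def test_zero_threshold_returns_everything_off_mean(self):
        load = np.array([[0.0], [0.0], [1.0], [-1.0]])
        out = rda_outlier_loci(self._model(load), significant_axes=[0], k_sd=0.0)
        assert set(out) == {2, 3}

    def test_no_significant_axes_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no significant axes"):
            out = rda_outlier_loci(self._model(np.ones((5, 1))), significant_axes=[])
        assert out.size == 0


class TestAssignTopVariable:
    def test_noise_free_monotone_locus_gets_positive_unit_r(self):
        rng = np.random.default_rng(12)
        env = pd.DataFrame(
            {"WT": rng.standard_normal(30), "AT": rng.standard_normal(30)}
        )
        dosage = (2 * (env["WT"].rank() / 30)).to_numpy()[:, None]
        res = assign_top_variable(["l1"], dosage, env)
        assert res.loc[0, "variable"] == "WT"
        assert res.loc[0, "r"] > 0.9

    def test_independent_locus_has_small_max_correlation(self):
        rng = np.random.default_rng(13)
        env = pd.DataFrame(rng.standard_normal((800, 3)), columns=list("ABC"))
        dosage = rng.binomial(2, 0.5, 800).astype(float)[:, None]
        res = assign_top_variable(["l1"], dosage, env)
        assert abs(res.loc[0, "r"]) < 0.2

    def test_identical_variables_tie_lexicographically(self):
        x = np.arange(10.0)
        env = pd.DataFrame({"B": x, "A": x})
        res = assign_top_variable(["l1"], x[:, None], env)
        assert res.loc[0, "variable"] == "A"
        assert bool(res.loc[0, "tie"])

    def test_zero_variance_locus_flagged(self):
        env = pd.DataFrame({"A": np.arange(5.0)})
        res = assign_top_variable(["l1"], np.ones((5, 1)), env)
        assert res.loc[0, "variable"] is None and bool(res.loc[0, "tie"])


class TestVarianceTest:
    def test_identity_response_saturates(self):
        X, _ = random_xy(14, n=20, q=3)
        res = rda_variance_test(X.copy(), X, n_perm=99, seed=1)
        assert res["R2"] == pytest.approx(1.0, abs=1e-10)
        assert res["p_global"] == pytest.approx(1 / 100)

    def test_independent_response_has_near_zero_adjusted_r2(self):
        X, Y = random_xy(15, n=60, L=40)
        res = rda_variance_test(Y, X, n_perm=99, seed=2)
        assert abs(res["adjusted_R2"]) < 0.1

    def test_permutation_p_stable_across_seeds(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((25, 2))
        Y = 0.4 * X @ rng.standard_normal((2, 30)) + rng.standard_normal((25, 30))
        p1 = rda_variance_test(Y, X, n_perm=999, seed=1)["p_global"]
        p2 = rda_variance_test(Y, X, n_perm=999, seed=2)["p_global"]
        assert abs(p1 - p2) < 0.02


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_agrees_with_vegan_reference(tmp_path):
    """Independent cross-check of R^2 / adjusted R^2 / eigenvalues against vegan."""
    rng = np.random.default_rng(21)
    X = rng.standard_normal((12, 3))
    Y = 0.8 * X @ rng.standard_normal((3, 6)) + rng.standard_normal((12, 6))
    pd.DataFrame(X, columns=list("abc")).to_csv(tmp_path / "X.csv", index=False)
    pd.DataFrame(Y).to_csv(tmp_path / "Y.csv", index=False)
    script = tmp_path / "rda.R"
    script.write_text(
        """
suppressMessages(library(vegan))
args <- commandArgs(trailingOnly=TRUE)
X <- scale(read.csv(args[1]))
Y <- read.csv(args[2])
m <- rda(Y ~ ., data=as.data.frame(X))
adj <- RsquareAdj(m)
cat(adj$r.squared, adj$adj.r.squared, eigenvals(m, model="constrained"), sep="\\n")
"""
    )
    out = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "X.csv"), str(tmp_path / "Y.csv")],
        capture_output=True, text=True, check=True,
    )
    vals = [float(v) for v in out.stdout.split()]
    model = fit_rda(Y, X)
    assert model.r_squared_ == pytest.approx(vals[0], abs=1e-6)
    assert model.adjusted_r_squared_ == pytest.approx(vals[1], abs=1e-6)
    np.testing.assert_allclose(model.eigenvalues_, vals[2:], atol=1e-6)
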