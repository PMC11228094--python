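"""Genomic-prediction kernels, GBLUP fits, scenarios and metrics."""

import numpy as np
import pandas as pd
import pytest

import pedigen as pg
from pedigen.containers import GenotypeMatrix, make_marker_map
from pedigen.lmm import fit_single_kernel
from pedigen.predict import (MODELS, additive_kernel, dominance_kernel,
                             fit_gblup, improvement_rate,
                             prediction_accuracy, project_inbreeding_effect,
                             run_train_scenarios)


def random_geno(rng, n, m):
    p = rng.uniform(0.1, 0.9, size=m)
    dose = rng.binomial(2, p, size=(n, m)).astype(np.float32) - 1.0
    mm = make_marker_map([f"s{j}" for j in range(m)], ["c1"] * m,
                         np.arange(m) * 100 + 100)
    return GenotypeMatrix(dose, [f"i{k}" for k in range(n)], mm)


def brute_force_additive(geno):
    d = geno.values + 1.0
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    n = d.shape[0]
    G = np.zeros((n, n))
    denom = 2.0 * np.sum(p * (1 - p))
    for i in range(n):
        for j in range(n):
            G[i, j] = np.sum((d[i] - 2 * p) * (d[j] - 2 * p)) / denom
    return G


def brute_force_dominance(geno):
    d = geno.values + 1.0
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    n = d.shape[0]
    tpq = 2 * p * (1 - p)
    H = (d == 1.0).astype(float) - tpq
    D = np.zeros((n, n))
    denom = np.sum(tpq ** 2)
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sum(H[i] * H[j]) / denom
    return D


class TestKernels:
    def test_clone_pair_offdiagonal_equals_diagonal(self):
        rng = np.random.default_rng(0)
        g = random_geno(rng, 12, 150)
        g.values[1] = g.values[0]
        G = additive_kernel(g).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=2e-6)

    def test_additive_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        g = random_geno(rng, 10, 20)
        G = additive_kernel(g).values
        B = brute_force_additive(g)
        assert np.allclose(G - 1e-6 * np.eye(10), B, atol=1e-5)

    def test_marker_duplication_leaves_G_unchanged(self):
        rng = np.random.default_rng(2)
        g = random_geno(rng, 15, 60)
        mm2 = make_marker_map([f"d{j}" for j in range(120)], ["c1"] * 120,
                              np.arange(120) * 100 + 100)
        g2 = GenotypeMatrix(np.hstack([g.values, g.values]), g.individuals,
                            mm2)
        assert np.allclose(additive_kernel(g).values,
                           additive_kernel(g2).values, atol=1e-5)

    def test_dominance_zero_for_fully_homozygous(self):
        rng = np.random.default_rng(3)
        g = random_geno(rng, 10, 50)
        g.values[g.values == 0.0] = 1.0  # erase heterozygotes
        with pytest.warns(UserWarning, match="heterozygous"):
            D = dominance_kernel(g).values
        assert np.allclose(D, 0.0)

    def test_dominance_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        g = random_geno(rng, 10, 20)
        D = dominance_kernel(g).values
        B = brute_force_dominance(g)
        assert np.allclose(D - 1e-6 * np.eye(10), B, atol=1e-5)

    def test_additive_dominance_uncorrelated_under_hwe(self):
        rng = np.random.default_rng(5)
        g = random_geno(rng, 80, 800)
        G = additive_kernel(g).values
        D = dominance_kernel(g).values
        iu = np.triu_indices(80, k=1)
        # per-pair products have a small positive bias O(1/m); the mean
        # off-diagonal product must vanish at this marker count
        assert abs(np.mean(G[iu] * D[iu])) < 0.01

    def test_single_individual_rejected(self):
        rng = np.random.default_rng(6)
        g = random_geno(rng, 1, 10)
        with pytest.raises(ValueError):
            additive_kernel(g)


class TestGBLUP:
    def test_rrblup_equivalence(self):
        """Single-kernel GBLUP predictions equal ridge regression on
        markers with the matched penalty (50 x 200 instance)."""
        rng = np.random.default_rng(7)
        n, m = 50, 200
        g = random_geno(rng, n, m)
        d = g.values + 1.0
        p = d.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        W = d[:, keep] - 2 * p[keep]
        c = 2.0 * np.sum(p[keep] * (1 - p[keep]))
        y = pd.Series(W @ rng.normal(0, 0.1, size=keep.sum())
                      + rng.normal(size=n), index=g.individuals)
        G = additive_kernel(g)
        gp = fit_gblup(y, None, {"additive": G}, "A")
        lam = gp.fit.sigma2["residual"] / (gp.fit.sigma2["additive"] / c)
        beta0 = gp.fit.beta[0]
        a_hat = np.linalg.solve(W.T @ W + lam * np.eye(keep.sum()),
                                W.T @ (y.values - beta0))
        ridge_pred = beta0 + W @ a_hat
        # ridge ignores the tiny diagonal stabilizer, hence loose atol
        assert np.allclose(gp.predictions.values, ridge_pred, atol=1e-2)

    def test_b_recovery_single_replicate(self):
        cfg = pg.SimConfig(seed=5, n_families=40, family_size_range=(10, 16))
        truth, ped, design = pg.simulate_population(cfg)
        arch = pg.TraitArchitecture(n_qtl=80, additive_var=1.0,
                                    inbreeding_effect_b=-2.0,
                                    residual_var=1.0)
        ph = pg.simulate_phenotypes(truth, arch, ped, [2000], seed=6)
        y = ph.groupby("individual")["value"].mean()
        geno = GenotypeMatrix(truth.genotypes().astype(np.float32),
                              truth.individuals, truth.marker_map)
        gp = fit_gblup(y, truth.true_inbreeding(),
                       {"additive": additive_kernel(geno)}, "AF")
        assert gp.inbreeding_b == pytest.approx(-2.0, abs=0.6)

    def test_zero_heritability_ratio_near_zero(self):
        rng = np.random.default_rng(8)
        g = random_geno(rng, 100, 300)
        G = additive_kernel(g)
        est = []
        for _ in range(5):
            y = pd.Series(rng.normal(size=100), index=g.individuals)
            est.append(fit_gblup(y, None, {"additive": G},
                                 "A").fit.heritability_ratio)
        assert np.mean(est) < 0.15

    def test_adf_collapses_to_af_without_dominance(self):
        cfg = pg.SimConfig(seed=6, n_families=20, family_size_range=(8, 12))
        truth, ped, design = pg.simulate_population(cfg)
        arch = pg.TraitArchitecture(n_qtl=60, additive_var=1.0,
                                    dominance_var=0.0,
                                    inbreeding_effect_b=-1.0,
                                    residual_var=0.5)
        ph = pg.simulate_phenotypes(truth, arch, ped, [2000], seed=7)
        y = ph.groupby("individual")["value"].mean()
        geno = GenotypeMatrix(truth.genotypes().astype(np.float32),
                              truth.individuals, truth.marker_map)
        kernels = {"additive": additive_kernel(geno),
                   "dominance": dominance_kernel(geno)}
        f = truth.true_inbreeding()
        adf = fit_gblup(y, f, kernels, "ADF")
        af = fit_gblup(y, f, {"additive": kernels["additive"]}, "AF")
        tot = sum(adf.fit.sigma2.values())
        assert adf.fit.sigma2["dominance"] / tot < 0.1
        r = np.corrcoef(adf.predictions.values, af.predictions.values)[0, 1]
        assert r > 0.99

    def test_constant_inbreeding_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        g = random_geno(rng, 30, 80)
        G = additive_kernel(g)
        y = pd.Series(rng.normal(size=30), index=g.individuals)
        f = pd.Series(0.1, index=g.individuals)
        with pytest.warns(UserWarning, match="constant"):
            gp = fit_gblup(y, f, {"additive": G}, "AF")
        assert gp.inbreeding_b is None

    def test_reml_matches_grid_search_oracle(self):
        """Spectral REML ratio equals a naive dense grid search."""
        from pedigen.lmm import _reml_neg_ll

        rng = np.random.default_rng(10)
        g = random_geno(rng, 60, 200)
        G = additive_kernel(g).values
        L = np.linalg.cholesky(G + 1e-6 * np.eye(60))
        y = L @ rng.normal(size=60) + rng.normal(size=60)
        X = np.ones((60, 1))
        fit = fit_single_kernel(y, X, G)
        d, U = np.linalg.eigh(G)
        d = np.clip(d, 0, None)
        ys, Xs = U.T @ y, U.T @ X
        grid = np.linspace(-8, 8, 20001)
        vals = [_reml_neg_ll(g_, d, ys, Xs) for g_ in grid]
        lam_grid = np.exp(grid[int(np.argmin(vals))])
        assert fit.extras["lambda"] == pytest.approx(lam_grid, rel=5e-3)


class TestMetrics:
    def test_negative_r_clamped_to_zero(self):
        pred = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        obs = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        r, rmse = prediction_accuracy(pred, obs)
        assert r == 0.0
        assert rmse > 0

    def test_improvement_rate_identity(self):
        assert improvement_rate(0.3, 0.3, 1.0, 1.0) == (1.0, 1.0)

    def test_improvement_rate_printed_values(self):
        r_ratio, rmse_ratio = improvement_rate(0.2437, 0.2362,
                                               0.8670, 0.9093)
        assert r_ratio == pytest.approx(1.0318, abs=5e-5)
        assert rmse_ratio == pytest.approx(1.0488, abs=5e-5)

    def test_improvement_rate_undefined(self):
        r_ratio, rmse_ratio = improvement_rate(0.1, 0.0, 1.0, 1.0)
        assert r_ratio is None

    def test_projection_identity_and_halving(self):
        assert project_inbreeding_effect(1.189, 1) == pytest.approx(1.189)
        assert project_inbreeding_effect(1.189, 2) == pytest.approx(
            0.594, abs=1e-3)  # 0.5945, printed as 0.594
        for g in range(1, 5):
            x = project_inbreeding_effect(3.0, g)
            assert project_inbreeding_effect(3.0, g + 1) == pytest.approx(
                x / 2)
        with pytest.raises(ValueError):
            project_inbreeding_effect(1.0, 0)


class TestScenarios:
    def test_training_on_test_set_rejected(self, small_pop):
        truth, ped, design = small_pop
        merged, _ = pg.merged_observed(truth)
        y = pd.Series(np.random.default_rng(0).normal(
            size=len(merged.individuals)), index=merged.individuals)
        # deliberately phenotype-complete: train pools would include the
        # dual-family test offspring only via a corrupted design
        bad = pg.PopulationDesign(
            parental_ids=list(design.parental_ids)
            + design.offspring_of(design.dual_families),
            families=design.families, members=design.members)
        with pytest.raises(ValueError, match="test individuals"):
            run_train_scenarios(merged, y, bad, scenarios=(2,))

    def test_scenarios_report_shape(self, small_pop):
        truth, ped, design = small_pop
        arch = pg.TraitArchitecture(n_qtl=40, additive_var=1.0,
                                    residual_var=1.0)
        ph = pg.simulate_phenotypes(truth, arch, ped, [2000], seed=9)
        y = ph.groupby("individual")["value"].mean()
        merged, _ = pg.merged_observed(truth)
        rep = run_train_scenarios(merged, y, design)
        assert list(rep["scenario"]) == ["Train 1", "Train 2", "Train 3"]
        assert (rep["r"] >= 0).all() and (rep["rmse"] > 0).all()
        assert (rep["n_test"] > 0).all()
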