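"""3-level meta-regression: closed forms, grid oracle, metafor cross-check."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from rsmeta.dataset import code_design_matrix
from rsmeta.meta3 import (
    Meta3Error,
    decompose_variance,
    fit_meta3,
    fit_meta3_coded,
    marginal_mean_es,
    meta3_loglik,
    r2_by_level,
    typical_sampling_variance,
)
from rsmeta.synthetic import (
    CovariateSpec,
    GeneratorConfig,
    IntRange,
    generate_effect_size_dataset,
)


class TestClosedForms:
    def test_degenerate_all_equal(self):
        y = np.full(12, 0.3)
        v = np.full(12, 0.01)
        cl = np.repeat([f"S{j}" for j in range(4)], 3)
        fit = fit_meta3(y, v, None, cl)
        assert fit.mu == pytest.approx(0.3, abs=1e-8)
        assert fit.tau2_level2 == pytest.approx(0.0, abs=1e-8)
        assert fit.tau2_level3 == pytest.approx(0.0, abs=1e-8)

    def test_fixed_effect_limit_inverse_variance_mean(self):
        """τ²₂ = τ²₃ = 0 pinned: μ̂ is the inverse-variance weighted mean."""
        y = np.array([0.2, 0.6])
        v = np.array([0.01, 0.04])
        fit = fit_meta3(y, v, None, np.array(["A", "B"]),
                        fix_tau2=0.0, fix_tau3=0.0)
        w = 1.0 / v
        assert fit.mu == pytest.approx(float((w * y).sum() / w.sum()), abs=1e-12)
        assert fit.se[0] == pytest.approx(np.sqrt(1.0 / w.sum()), abs=1e-12)

    def test_negative_variance_clipped_at_zero(self):
        # homogeneous data far tighter than its sampling variances
        y = np.array([0.30, 0.30, 0.31, 0.29, 0.30, 0.30])
        v = np.full(6, 0.05)
        cl = np.array(["A", "A", "B", "B", "C", "C"])
        fit = fit_meta3(y, v, None, cl)
        assert fit.tau2_level2 >= 0.0 and fit.tau2_level3 >= 0.0
        assert fit.tau2_level2 < 1e-6 and fit.tau2_level3 < 1e-6

    def test_sampling_var_positive_required(self):
        with pytest.raises(Meta3Error):
            fit_meta3(np.array([0.1, 0.2]), np.array([0.01, 0.0]), None,
                      np.array(["A", "B"]))


class TestGridOracle:
    def test_reml_optimum_matches_grid(self):
        """REML optimum of a 3-effect toy matches dense (τ²₂, τ²₃) search."""
        y = np.array([0.10, 0.45, 0.30])
        v = np.array([0.02, 0.03, 0.015])
        cl = np.array(["A", "A", "B"])
        fit = fit_meta3(y, v, None, cl)
        X = np.ones((3, 1))
        grid = np.linspace(0.0, 0.3, 121)
        best_ll, best = -np.inf, None
        for t2 in grid:
            for t3 in grid:
                ll = meta3_loglik(y, v, X, cl, t2, t3)
                if ll > best_ll:
                    best_ll, best = ll, (t2, t3)
        # refine around the coarse winner
        g2 = np.linspace(max(0, best[0] - 0.005), best[0] + 0.005, 81)
        g3 = np.linspace(max(0, best[1] - 0.005), best[1] + 0.005, 81)
        for t2 in g2:
            for t3 in g3:
                ll = meta3_loglik(y, v, X, cl, t2, t3)
                if ll > best_ll:
                    best_ll, best = ll, (t2, t3)
        assert fit.loglik >= best_ll - 1e-5
        assert fit.tau2_level2 == pytest.approx(best[0], abs=2e-4)
        assert fit.tau2_level3 == pytest.approx(best[1], abs=2e-4)

    def test_loglik_matches_dense_matrix_evaluation(self):
        """Sherman–Morrison likelihood equals the brute-force dense version."""
        rng = np.random.default_rng(3)
        n = 12
        y = rng.normal(0.3, 0.2, n)
        v = rng.uniform(0.01, 0.05, n)
        cl = np.repeat([f"S{j}" for j in range(4)], 3)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        t2, t3 = 0.02, 0.03
        V = np.diag(v + t2)
        for j in range(4):
            idx = np.arange(3 * j, 3 * j + 3)
            V[np.ix_(idx, idx)] += t3
        Vi = np.linalg.inv(V)
        gamma = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ gamma
        p = X.shape[1]
        dense = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(X.T @ Vi @ X)[1]
            + r @ Vi @ r
        )
        assert meta3_loglik(y, v, X, cl, t2, t3) == pytest.approx(dense, abs=1e-9)


@pytest.mark.parametrize("method", ["REML", "ML"])
def test_metafor_cross_check(tmp_path, method, small_magnitude_dataset):
    """Estimates agree with metafor::rma.mv (3-level) and rma (2-level
    reduction with τ²₃ pinned to zero) on the same data."""
    df = small_magnitude_dataset.effects.iloc[:120].copy()
    csv = tmp_path / "toy.csv"
    df.to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(metafor))
    d <- read.csv("{csv}")
    d$eff <- seq_len(nrow(d))
    m <- rma.mv(d_abs, sampling_var, random = list(~1|sample_id, ~1|eff),
                data=d, method="{method}")
    m2 <- rma(d_abs, sampling_var, data=d, method="{method}")
    cat(coef(m), m$sigma2[2], m$sigma2[1], coef(m2), m2$tau2, sep=",")
    """
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    mu_r, t2_r, t3_r, mu2_r, tau2_r = map(float, out.stdout.strip().split(","))

    fit = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                    df.sample_id.to_numpy(), method=method)
    assert fit.mu == pytest.approx(mu_r, abs=1e-5)
    assert fit.tau2_level2 == pytest.approx(t2_r, abs=1e-5)
    assert fit.tau2_level3 == pytest.approx(t3_r, abs=1e-5)

    flat = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                     df.effect_id.to_numpy(), method=method, fix_tau3=0.0)
    assert flat.mu == pytest.approx(mu2_r, abs=1e-6)
    assert flat.tau2_level2 == pytest.approx(tau2_r, abs=1e-6)


class TestDecomposition:
    def test_tau_zero_gives_level1_share_one(self):
        y = np.full(8, 0.3)
        v = np.full(8, 0.02)
        cl = np.repeat(["A", "B", "C", "D"], 2)
        fit = fit_meta3(y, v, None, cl)
        dec = decompose_variance(fit, v)
        assert dec.share_level1 == pytest.approx(1.0, abs=1e-6)
        assert dec.share_level1 + dec.share_level2 + dec.share_level3 == pytest.approx(
            1.0, abs=1e-9
        )

    def test_typical_sampling_variance_equal_case(self):
        # with equal σ² the typical value is σ² itself
        assert typical_sampling_variance(np.full(10, 0.004)) == pytest.approx(0.004)

    def test_decomposition_recovers_generative_shares(self):
        cfg = GeneratorConfig(
            n_samples=150, effects_per_sample=IntRange(5, 5),
            es_mu=0.30, es_tau2_level3=0.029, es_tau2_level2=0.019,
            participant_n=IntRange(57, 410), multi_study_fraction=0.0, seed=21,
        )
        data = generate_effect_size_dataset(cfg)
        df = data.effects
        fit = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                        df.sample_id.to_numpy())
        dec = decompose_variance(fit, df.sampling_var.to_numpy())
        # sample level dominates, then effect level, small participant share
        assert dec.share_level3 == pytest.approx(0.55, abs=0.12)
        assert dec.share_level2 == pytest.approx(0.36, abs=0.12)
        assert dec.share_level1 == pytest.approx(0.09, abs=0.06)


class TestR2ByLevel:
    def test_identity_zero(self, small_magnitude_dataset):
        df = small_magnitude_dataset.effects
        fit = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                        df.sample_id.to_numpy())
        assert r2_by_level(fit, fit) == (0.0, 0.0)

    def test_moderator_explaining_level3_variance(self):
        """A sample-level moderator that generates all τ²₃ drives R²₃ → 1."""
        cfg = GeneratorConfig(
            n_samples=250, effects_per_sample=IntRange(4, 4),
            covariate_spec=[CovariateSpec("g", ["a", "b"], [0.5, 0.5], "sample")],
            es_gamma={"g:b": 0.40},
            es_mu=0.30, es_tau2_level3=0.0, es_tau2_level2=0.01,
            participant_n=IntRange(200, 400), multi_study_fraction=0.0, seed=9,
        )
        data = generate_effect_size_dataset(cfg)
        df = data.effects
        null = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                         df.sample_id.to_numpy())
        coded = code_design_matrix(df, {"g": ["a", "b"]}, response="d_abs",
                                   sampling_var="sampling_var")
        full = fit_meta3_coded(coded)
        r2_l2, r2_l3 = r2_by_level(null, full)
        assert null.tau2_level3 > 0.03  # moderator-induced heterogeneity
        assert r2_l3 > 0.9

    def test_undefined_when_null_tau_zero(self):
        y = np.full(8, 0.3)
        v = np.full(8, 0.02)
        cl = np.repeat(["A", "B", "C", "D"], 2)
        fit = fit_meta3(y, v, None, cl)
        assert r2_by_level(fit, fit) == (None, None)


class TestMarginalMeans:
    def test_intercept_only_constant(self, small_magnitude_dataset):
        df = small_magnitude_dataset.effects
        coded = code_design_matrix(df, {"g": ["a", "b"]}, response="d_abs",
                                   sampling_var="sampling_var")
        fit = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                        df.sample_id.to_numpy())
        # pad fit names so the marginal code can align (no moderators -> μ̂)
        est_a = marginal_mean_es(fit, coded, "g", "a").estimate
        est_b = marginal_mean_es(fit, coded, "g", "b").estimate
        assert est_a == pytest.approx(fit.mu, abs=1e-10)
        assert est_b == pytest.approx(fit.mu, abs=1e-10)

    def test_binary_moderator_hand_calc(self, small_magnitude_dataset):
        df = small_magnitude_dataset.effects
        coded = code_design_matrix(df, {"g": ["a", "b"]}, response="d_abs",
                                   sampling_var="sampling_var")
        fit = fit_meta3_coded(coded)
        mu, gam = fit.mu, float(fit.params["g:b"])
        assert marginal_mean_es(fit, coded, "g", "a").estimate == pytest.approx(
            mu, abs=1e-10
        )
        assert marginal_mean_es(fit, coded, "g", "b").estimate == pytest.approx(
            mu + gam, abs=1e-10
        )

    def test_reference_reparameterization_invariance(self, small_magnitude_dataset):
        """Recoding the dummy reference leaves predicted category means fixed."""
        df = small_magnitude_dataset.effects
        coded_a = code_design_matrix(df, {"g": ["a", "b"]}, response="d_abs",
                                     sampling_var="sampling_var")
        coded_b = code_design_matrix(df, {"g": ["a", "b"]}, reference={"g": "b"},
                                     response="d_abs", sampling_var="sampling_var")
        fit_a, fit_b = fit_meta3_coded(coded_a), fit_meta3_coded(coded_b)
        for cat in ("a", "b"):
            assert marginal_mean_es(fit_a, coded_a, "g", cat).estimate == pytest.approx(
                marginal_mean_es(fit_b, coded_b, "g", cat).estimate, abs=1e-7
            )
        assert fit_a.tau2_level2 == pytest.approx(fit_b.tau2_level2, abs=1e-8)
        assert fit_a.tau2_level3 == pytest.approx(fit_b.tau2_level3, abs=1e-8)


def test_parameter_recovery_single_dataset():
    cfg = GeneratorConfig(
        n_samples=200, effects_per_sample=IntRange(5, 5),
        es_mu=0.30, es_tau2_level3=0.029, es_tau2_level2=0.019,
        participant_n=IntRange(57, 410), multi_study_fraction=0.0, seed=33,
    )
    data = generate_effect_size_dataset(cfg)
    df = data.effects
    fit = fit_meta3(df.d_abs.to_numpy(), df.sampling_var.to_numpy(), None,
                    df.sample_id.to_numpy())
    assert fit.mu == pytest.approx(0.30, abs=0.04)
    assert fit.tau2_level3 == pytest.approx(0.029, abs=0.015)
    assert fit.tau2_level2 == pytest.approx(0.019, abs=0.008)
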