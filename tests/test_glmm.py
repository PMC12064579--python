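"""2-level logistic GLMM: quadrature oracles, boundary behavior, latent R²."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rsmeta.dataset import code_design_matrix
from rsmeta.glmm import (
    LATENT_RESIDUAL_VAR,
    GlmmSpec,
    RankDeficientError,
    fit_glmm,
    glmm_loglik,
    latent_r2,
    standardized_solution,
)
from rsmeta.synthetic import generate_detection_dataset

from conftest import detection_config


def dense_grid_loglik(coded, y, beta, tau2, grid=200_001, span=12.0):
    """Brute-force marginal log-likelihood by trapezoid integration over u."""
    X = np.column_stack([np.ones(coded.n), coded.X.to_numpy()])
    eta0 = X @ np.asarray(beta)
    u = np.linspace(-span, span, grid)
    phi = np.exp(-(u**2) / (2 * tau2)) / np.sqrt(2 * np.pi * tau2)
    total = 0.0
    for cl in pd.unique(coded.cluster):
        m = coded.cluster == cl
        ll_u = (
            y[m, None] * (eta0[m, None] + u[None, :])
            - np.logaddexp(0, eta0[m, None] + u[None, :])
        ).sum(axis=0)
        total += np.log(np.trapezoid(np.exp(ll_u) * phi, u))
    return total


class TestQuadratureOracle:
    @pytest.mark.parametrize(
        "beta, tau2",
        [([0.3, -0.7], 0.8), ([0.0, 0.0], 0.3), ([-1.0, 1.5], 2.0)],
    )
    def test_matches_dense_grid(self, toy_binary_frame, toy_binary_coded, beta, tau2):
        y = toy_binary_frame["detected"].to_numpy(dtype=float)
        ghq = glmm_loglik(toy_binary_coded, y, np.asarray(beta), tau2)
        dense = dense_grid_loglik(toy_binary_coded, y, beta, tau2)
        assert ghq == pytest.approx(dense, abs=1e-6)

    def test_matches_at_optimum(self, toy_binary_frame, toy_binary_coded):
        fit = fit_glmm(toy_binary_coded)
        y = toy_binary_frame["detected"].to_numpy(dtype=float)
        if fit.tau2 > 1e-8:
            dense = dense_grid_loglik(toy_binary_coded, y, fit.beta, fit.tau2)
            assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_node_count_convergence(self, small_detection_dataset):
        """21-node adaptive result within 1e-6 of 101 nodes on a fixed fit."""
        df = small_detection_dataset.effects
        coded = code_design_matrix(
            df, {"x1": ["a", "b"], "x2": ["a", "b"]}, response="detected"
        )
        y = df["detected"].to_numpy(dtype=float)
        beta = np.array([0.1, 0.8, -0.5])
        lls = [
            glmm_loglik(coded, y, beta, 1.0, quadrature_points=nq)
            for nq in (11, 21, 101)
        ]
        assert abs(lls[1] - lls[2]) < 1e-6
        assert abs(lls[0] - lls[2]) >= abs(lls[1] - lls[2]) - 1e-9


class TestBoundary:
    def _frame(self):
        y = [1, 0, 1, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1, 0, 0, 1]
        return pd.DataFrame(
            {
                "effect_id": [f"e{i}" for i in range(16)],
                "study_id": "s",
                "sample_id": list("AAAABBBBCCCCDDDD"),
                "detected": y,
                "x": ["a", "a", "b", "b"] * 4,
            }
        )

    def test_tau2_zero_reduces_to_plain_logistic(self):
        df = self._frame()
        coded = code_design_matrix(df, {"x": ["a", "b"]}, response="detected")
        fit = fit_glmm(coded)
        X = np.column_stack([np.ones(16), coded.X.to_numpy()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(df["detected"], X).fit(disp=0, method="newton", tol=1e-12)
        assert fit.tau2 < 1e-8
        assert np.abs(fit.beta - res.params.to_numpy()).max() < 1e-6
        assert fit.loglik == pytest.approx(res.llf, abs=1e-8)

    def test_loglik_at_zero_is_plain_logistic(self):
        df = self._frame()
        coded = code_design_matrix(df, {"x": ["a", "b"]}, response="detected")
        beta = np.array([0.2, -0.4])
        eta = np.column_stack([np.ones(16), coded.X.to_numpy()]) @ beta
        y = df["detected"].to_numpy(dtype=float)
        plain = float(np.sum(y * eta - np.logaddexp(0, eta)))
        assert glmm_loglik(coded, y, beta, 0.0) == pytest.approx(plain, abs=1e-12)


def test_intercept_only_tau2_zero_generative(small_detection_dataset):
    """τ² = 0 data: fitted intercept ≈ logit of the observed proportion."""
    cfg = detection_config(seed=5, tau2_sample=0.0, beta={}, covariate_spec=[])
    data = generate_detection_dataset(cfg)
    coded = code_design_matrix(data.effects, {}, response="detected")
    fit = fit_glmm(coded)
    prop = data.effects["detected"].mean()
    assert fit.tau2 < 0.02
    assert fit.beta[0] == pytest.approx(np.log(prop / (1 - prop)), abs=0.05)


def test_parameter_recovery_single_dataset(small_detection_dataset):
    df = small_detection_dataset.effects
    coded = code_design_matrix(
        df, {"x1": ["a", "b"], "x2": ["a", "b"]}, response="detected"
    )
    fit = fit_glmm(coded)
    assert fit.converged
    # single dataset at 60x10: generous 3-SE style windows
    assert fit.params["x1:b"] == pytest.approx(0.8, abs=0.45)
    assert fit.params["x2:b"] == pytest.approx(-0.5, abs=0.45)
    assert fit.tau2 == pytest.approx(1.0, abs=0.75)
    assert (fit.se[np.isfinite(fit.se)] > 0).all()


def test_rank_deficiency_names_columns():
    df = pd.DataFrame(
        {
            "effect_id": [f"e{i}" for i in range(8)],
            "study_id": "s",
            "sample_id": list("AABBCCDD"),
            "detected": [1, 0, 1, 1, 0, 0, 1, 0],
            "x": ["a", "b"] * 4,
            "x_copy": ["a", "b"] * 4,
        }
    )
    coded = code_design_matrix(
        df, {"x": ["a", "b"], "x_copy": ["a", "b"]}, response="detected"
    )
    with pytest.raises(RankDeficientError, match="x_copy"):
        fit_glmm(coded)


def test_lrt_nonnegative(small_detection_dataset):
    """The full model's maximized loglik dominates the nested null's."""
    df = small_detection_dataset.effects
    full = fit_glmm(
        code_design_matrix(df, {"x1": ["a", "b"], "x2": ["a", "b"]}, response="detected")
    )
    null = fit_glmm(code_design_matrix(df, {}, response="detected"))
    assert full.loglik >= null.loglik - 1e-8


class TestLatentR2:
    def test_null_vs_null_zero(self, small_detection_dataset):
        df = small_detection_dataset.effects
        coded = code_design_matrix(df, {}, response="detected")
        fit = fit_glmm(coded)
        r2 = latent_r2(fit, fit, coded)
        assert r2.r2_total == pytest.approx(0.0, abs=1e-12)
        assert r2.r2_effect == pytest.approx(0.0, abs=1e-12)
        assert r2.r2_sample == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_total_r2(self):
        """Effect-level binary covariates: R² ≈ var(Xβ)/(var(Xβ)+τ²+π²/3)."""
        cfg = detection_config(seed=77, n_samples=150)
        data = generate_detection_dataset(cfg)
        variables = {"x1": ["a", "b"], "x2": ["a", "b"]}
        coded = code_design_matrix(data.effects, variables, response="detected")
        full = fit_glmm(coded)
        null = fit_glmm(code_design_matrix(data.effects, {}, response="detected"))
        r2 = latent_r2(null, full, coded)
        var_xb = 0.25 * 0.8**2 + 0.25 * 0.5**2
        analytic = var_xb / (var_xb + 1.0 + LATENT_RESIDUAL_VAR)
        assert r2.r2_total == pytest.approx(analytic, abs=0.02)

    def test_mismatched_rows_raise(self, small_detection_dataset, toy_binary_coded):
        df = small_detection_dataset.effects
        coded = code_design_matrix(df, {}, response="detected")
        fit = fit_glmm(coded)
        toy_fit = fit_glmm(toy_binary_coded)
        with pytest.raises(Exception, match="same data"):
            latent_r2(fit, toy_fit, coded)


class TestStandardizedSolution:
    def test_single_predictor_identity(self):
        """With one predictor, standardized β equals the latent correlation."""
        cfg = detection_config(seed=55, beta={"x1:b": 0.8},
                               covariate_spec=detection_config().covariate_spec[:1])
        data = generate_detection_dataset(cfg)
        coded = code_design_matrix(data.effects, {"x1": ["a", "b"]},
                                   response="detected")
        fit = fit_glmm(coded)
        std_beta, corr = standardized_solution(fit, coded)
        assert std_beta["x1:b"] == pytest.approx(corr["x1:b"], abs=1e-10)

    def test_orthogonal_two_predictor_hand_scaling(self):
        """Orthogonal design: std β_j = β_j sd_j / sd(y*) computed by hand."""
        df = pd.DataFrame(
            {
                "effect_id": [f"e{i}" for i in range(8)],
                "study_id": "s",
                "sample_id": list("AABBCCDD"),
                "detected": [1, 0, 1, 1, 0, 0, 1, 0],
                "x1": ["a", "a", "b", "b"] * 2,
                "x2": ["a", "b"] * 4,
            }
        )
        coded = code_design_matrix(df, {"x1": ["a", "b"], "x2": ["a", "b"]},
                                   response="detected")
        fit = fit_glmm(coded)
        std_beta, corr = standardized_solution(fit, coded)
        X = np.column_stack([np.ones(8), coded.X.to_numpy()])
        eta = X @ fit.beta
        sd_y = np.sqrt(np.var(eta) + fit.tau2 + LATENT_RESIDUAL_VAR)
        for col in ("x1:b", "x2:b"):
            sd_x = coded.X[col].std(ddof=0)
            assert std_beta[col] == pytest.approx(
                fit.params[col] * sd_x / sd_y, abs=1e-10
            )
        # orthogonal balanced design: r_j = std β_j exactly
        assert corr["x1:b"] == pytest.approx(std_beta["x1:b"], abs=1e-10)

    def test_zero_variance_predictor_warns(self, toy_binary_frame):
        df = toy_binary_frame.copy()
        coded = code_design_matrix(df, {"x": ["a", "b"]}, response="detected")
        fit = fit_glmm(coded)
        coded.X["x:b"] = 0.0  # degrade after fitting
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            std_beta, _ = standardized_solution(fit, coded)
        assert len(std_beta) == 0
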