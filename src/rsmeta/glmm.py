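"""Two-level random-intercept logistic regression by adaptive Gauss–Hermite ML.

Detection of a response-shift effect is binary and effects cluster within
samples, so the working model is

    logit P(y_ij = 1 | u_j) = x_ij' β + u_j,      u_j ~ N(0, τ²),

with i indexing effects and j samples.  The marginal likelihood integrates
the random intercept out of each cluster's Bernoulli likelihood; the
integral is evaluated by *adaptive* Gauss–Hermite quadrature: nodes are
recentred at each cluster's posterior mode and rescaled by the posterior
curvature, which keeps a modest node count accurate even for large clusters.

On the latent-response view, y*_ij = x'β + u_j + e_ij with e_ij standard
logistic (variance π²/3); this scale carries the explained-variance
computations: total latent variance = var(x'β) + τ² + π²/3, standardized
coefficients rescale by predictor SD / latent SD, and R² is split into
effect- and sample-level parts via the within-/between-cluster decomposition
of the fixed linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .dataset import CodedMatrix

LATENT_RESIDUAL_VAR = np.pi**2 / 3.0

INTERCEPT = "(Intercept)"


class GlmmError(RuntimeError):
    pass


class RankDeficientError(GlmmError):
    """Design matrix is collinear; message names the offending columns."""


@dataclass
class GlmmSpec:
    """Estimation settings for the 2-level logistic fit."""

    quadrature_points: int = 15
    max_iter: int = 500
    tol: float = 1e-9

    def __post_init__(self):
        if self.quadrature_points < 5:
            raise ValueError("quadrature_points must be >= 5")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class GlmmFit:
    """Maximum-likelihood fit of the 2-level random-intercept logistic model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    loglik: float
    var_fixed: float
    converged: bool
    n_effects: int
    n_samples: int
    vcov: Optional[np.ndarray] = None
    tau2_se: Optional[float] = None
    latent_residual: float = LATENT_RESIDUAL_VAR
    columns_by_variable: dict = field(default_factory=dict)
    message: str = ""

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)

    @property
    def coef(self) -> pd.Series:
        """Coefficients excluding the intercept (shared-term comparisons)."""
        return self.params.drop(INTERCEPT)

    def wald_test(self, columns: Sequence[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the listed coefficients are zero."""
        idx = [self.names.index(c) for c in columns]
        b = self.beta[idx]
        V = self.vcov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))

    @property
    def variable_p(self) -> dict[str, float]:
        """Joint Wald p-value per variable block (selection interface)."""
        out = {}
        for var, cols in self.columns_by_variable.items():
            if cols:
                out[var] = self.wald_test(cols)[2]
        return out

    def summary(self) -> pd.DataFrame:
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": z,
             "p": 2 * stats.norm.sf(np.abs(z))},
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {n: float(b) for n, b in zip(self.names, self.beta)},
            "se": {n: float(s) for n, s in zip(self.names, self.se)},
            "tau2": float(self.tau2),
            "loglik": float(self.loglik),
            "var_fixed": float(self.var_fixed),
            "latent_residual": float(self.latent_residual),
            "converged": bool(self.converged),
            "n_effects": int(self.n_effects),
            "n_samples": int(self.n_samples),
        }


# ---------------------------------------------------------------------------
# marginal log-likelihood machinery


def _bernoulli_loglik_by_cluster(eta: np.ndarray, y: np.ndarray, codes: np.ndarray,
                                 n_clusters: int) -> np.ndarray:
    # ll_i = y*eta - log(1 + exp(eta)), numerically stable
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(codes, weights=ll, minlength=n_clusters)


class _MarginalLoglik:
    """Adaptive-GHQ marginal log-likelihood of (β, s), s = sqrt(τ²).

    Cluster posterior modes are cached across evaluations so the Newton mode
    search is warm-started during optimization and finite differencing.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                 n_clusters: int, nq: int):
        self.X, self.y, self.codes, self.n_clusters = X, y, codes, n_clusters
        z, w = np.polynomial.hermite.hermgauss(nq)
        self.z = z
        self.logw_adj = np.log(w) + z**2  # absorbed e^{z²} factor
        self.u_cache = np.zeros(n_clusters)

    def _modes(self, eta0: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature scale of u_j given data, per cluster."""
        codes, y, nclus = self.codes, self.y, self.n_clusters
        u = self.u_cache.copy()
        inv_s2 = 1.0 / (s * s)
        for _ in range(100):
            eta = eta0 + u[codes]
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = np.bincount(codes, weights=y - p, minlength=nclus) - u * inv_s2
            info = np.bincount(codes, weights=p * (1 - p), minlength=nclus) + inv_s2
            step = grad / info
            # damp large Newton steps for robustness far from the mode
            step = np.clip(step, -5.0, 5.0)
            u += step
            if np.max(np.abs(step)) < 1e-11:
                break
        self.u_cache = u
        sd = 1.0 / np.sqrt(info)
        return u, sd

    def loglik(self, beta: np.ndarray, s: float) -> float:
        eta0 = self.X @ beta
        if s < 1e-10:
            # τ² = 0: the model is ordinary logistic regression
            return float(np.sum(self.y * eta0 - np.logaddexp(0.0, eta0)))
        u_hat, sd = self._modes(eta0, s)
        nclus = self.n_clusters
        log_phi_const = -np.log(s) - 0.5 * np.log(2.0 * np.pi)
        # h_jk = sum_i ll_i(u_jk) + log phi(u_jk; 0, s²), at adapted nodes
        h = np.empty((len(self.z), nclus))
        for k, zk in enumerate(self.z):
            u_k = u_hat + np.sqrt(2.0) * sd * zk
            cll = _bernoulli_loglik_by_cluster(eta0 + u_k[self.codes], self.y,
                                               self.codes, nclus)
            h[k] = cll - 0.5 * (u_k / s) ** 2 + log_phi_const
        log_lj = logsumexp(h + self.logw_adj[:, None], axis=0)
        log_lj += 0.5 * np.log(2.0) + np.log(sd)
        return float(np.sum(log_lj))


def glmm_loglik(data: CodedMatrix, response: np.ndarray, beta: np.ndarray,
                tau2: float, quadrature_points: int = 15) -> float:
    """Marginal log-likelihood at given parameters (oracle-testing surface).

    ``beta`` is ordered (intercept, data.X columns); ``tau2`` is the
    sample-level intercept variance.
    """
    X = np.column_stack([np.ones(data.n), data.X.to_numpy()])
    codes, n_clusters = _cluster_codes(data.cluster)
    prob = _MarginalLoglik(X, np.asarray(response, float), codes, n_clusters,
                           quadrature_points)
    return prob.loglik(np.asarray(beta, float), float(np.sqrt(tau2)))


def _cluster_codes(cluster: np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(cluster)
    return codes.astype(np.int64), len(uniq)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {cols}")


def fit_glmm(data: CodedMatrix, spec: Optional[GlmmSpec] = None,
             start: Optional[np.ndarray] = None) -> GlmmFit:
    """Fit the 2-level random-intercept logistic model by adaptive-GHQ ML.

    ``data.y`` is the binary response and ``data.cluster`` the sample id.
    ``start`` optionally warm-starts (β..., s) from a previous fit, e.g.
    across bootstrap replicates.
    """
    spec = spec or GlmmSpec()
    if data.y is None:
        raise GlmmError("CodedMatrix has no response vector")
    y = np.asarray(data.y, dtype=float)
    X = np.column_stack([np.ones(data.n), data.X.to_numpy(dtype=float)])
    names = [INTERCEPT] + list(data.X.columns)
    _check_rank(X, names)
    codes, n_clusters = _cluster_codes(data.cluster)
    if n_clusters < 2:
        raise GlmmError("need at least 2 clusters")

    prob = _MarginalLoglik(X, y, codes, n_clusters, spec.quadrature_points)
    p = X.shape[1]

    if start is not None:
        x0 = np.asarray(start, dtype=float)
    else:
        beta0 = _logistic_irls(X, y)
        x0 = np.append(beta0, 0.7)

    def negll(theta: np.ndarray) -> float:
        return -prob.loglik(theta[:-1], theta[-1])

    bounds = [(None, None)] * p + [(0.0, 25.0)]
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": spec.max_iter, "ftol": spec.tol, "gtol": 1e-8},
    )
    theta = res.x
    beta, s = theta[:-1], theta[-1]
    loglik = -res.fun

    # observed-information SEs via central finite-difference Hessian
    at_boundary = s < 1e-6
    free = np.arange(p) if at_boundary else np.arange(p + 1)
    H = _fd_hessian(negll, theta, free)
    se = np.full(p, np.nan)
    vcov_full = None
    tau2_se = None
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        if at_boundary:
            se = np.sqrt(diag)
            vcov_full = cov
        else:
            se = np.sqrt(diag[:p])
            vcov_full = cov[:p, :p]
            # var(τ²) = (2s)² var(s) by the delta method
            tau2_se = float(2.0 * s * np.sqrt(diag[p])) if np.isfinite(diag[p]) else None
    except np.linalg.LinAlgError:
        pass

    eta_fixed = X @ beta
    return GlmmFit(
        names=names,
        beta=beta,
        se=se,
        tau2=float(s * s),
        loglik=float(loglik),
        var_fixed=float(np.var(eta_fixed)),
        converged=bool(res.success),
        n_effects=len(y),
        n_samples=n_clusters,
        vcov=vcov_full,
        tau2_se=tau2_se,
        columns_by_variable=dict(data.columns_by_variable),
        message=str(res.message),
    )


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Plain logistic regression (starting values), ridge-stabilized IRLS."""
    p = X.shape[1]
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _fd_hessian(f, x: np.ndarray, free: np.ndarray, h_rel: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of f over the ``free`` coordinates of x."""
    k = len(free)
    h = h_rel * np.maximum(1.0, np.abs(x[free]))
    H = np.empty((k, k))
    f0 = f(x)
    for a in range(k):
        ia = free[a]
        xp, xm = x.copy(), x.copy()
        xp[ia] += h[a]
        xm[ia] -= h[a]
        H[a, a] = (f(xp) - 2.0 * f0 + f(xm)) / h[a] ** 2
        for b in range(a + 1, k):
            ib = free[b]
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[ia] += h[a]; xpp[ib] += h[b]
            xpm[ia] += h[a]; xpm[ib] -= h[b]
            xmp[ia] -= h[a]; xmp[ib] += h[b]
            xmm[ia] -= h[a]; xmm[ib] -= h[b]
            H[a, b] = H[b, a] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[a] * h[b])
    return H


# ---------------------------------------------------------------------------
# latent-scale explained variance


@dataclass
class VarianceExplained:
    """Latent-scale R² of a fitted model relative to the null model."""

    r2_total: float
    r2_effect: float
    r2_sample: Optional[float]
    var_fixed: float
    var_within: float
    var_between: float
    tau2_null: float
    tau2_full: float
    level_of_variable: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r2_total": self.r2_total,
            "r2_effect": self.r2_effect,
            "r2_sample": self.r2_sample,
            "var_fixed": self.var_fixed,
            "var_within": self.var_within,
            "var_between": self.var_between,
            "tau2_null": self.tau2_null,
            "tau2_full": self.tau2_full,
        }


def latent_r2(fit_null: GlmmFit, fit_full: GlmmFit, data: CodedMatrix,
              level_of_variable: Optional[dict] = None) -> VarianceExplained:
    """Explained variance on the latent logistic scale, split by level.

    The fixed linear predictor x'β̂ of the full model is decomposed into its
    between-cluster part (cluster means) and within-cluster deviations:

    * effect-level R² = var_W / (var_W + π²/3) — share of within-sample
      latent variance captured by effect-level variation of the predictor;
    * sample-level R² = (var_B + τ²_null − τ²_full) / τ²_null — between-
      sample predictor variance plus the reduction of the random-intercept
      variance, relative to the null model's sample-level variance (may be
      negative; undefined if τ²_null = 0);
    * total R² = var(x'β̂) / (var(x'β̂) + τ²_full + π²/3).
    """
    if fit_null.n_effects != fit_full.n_effects or fit_null.n_samples != fit_full.n_samples:
        raise GlmmError("null and full fits must come from the same data rows")
    if data.n != fit_full.n_effects:
        raise GlmmError("data rows do not match the fits")
    X = np.column_stack([np.ones(data.n), data.X.to_numpy(dtype=float)])
    eta = X @ fit_full.beta
    codes, n_clusters = _cluster_codes(data.cluster)
    cl_mean = np.bincount(codes, weights=eta, minlength=n_clusters) / np.bincount(
        codes, minlength=n_clusters
    )
    between = cl_mean[codes]
    var_b = float(np.var(between))
    var_w = float(np.var(eta - between))
    var_f = float(np.var(eta))
    r2_effect = var_w / (var_w + LATENT_RESIDUAL_VAR)
    tau2_null, tau2_full = fit_null.tau2, fit_full.tau2
    r2_sample = (
        (var_b + tau2_null - tau2_full) / tau2_null if tau2_null > 0 else None
    )
    r2_total = var_f / (var_f + tau2_full + LATENT_RESIDUAL_VAR)
    return VarianceExplained(
        r2_total=r2_total,
        r2_effect=r2_effect,
        r2_sample=r2_sample,
        var_fixed=var_f,
        var_within=var_w,
        var_between=var_b,
        tau2_null=tau2_null,
        tau2_full=tau2_full,
        level_of_variable=dict(level_of_variable or {}),
    )


def standardized_solution(
    fit: GlmmFit, data: CodedMatrix
) -> tuple[pd.Series, pd.Series]:
    """Standardized coefficients and latent predictor–response correlations.

    On the latent scale sd(y*) = sqrt(var(x'β̂) + τ̂² + π²/3); each
    coefficient is rescaled by sd(x_j)/sd(y*), and the latent correlation of
    predictor j with y* is cov(x_j, x'β̂)/(sd(x_j)·sd(y*)) (the random terms
    are independent of x).  Zero-variance predictors are excluded with a
    warning.  These two vectors feed the Pratt-index partition.
    """
    if not fit.converged:
        warnings.warn("standardizing a non-converged fit", RuntimeWarning)
    Xd = data.X.to_numpy(dtype=float)
    X = np.column_stack([np.ones(data.n), Xd])
    eta = X @ fit.beta
    sd_latent = np.sqrt(np.var(eta) + fit.tau2 + LATENT_RESIDUAL_VAR)
    cols = list(data.X.columns)
    sd_x = Xd.std(axis=0)
    keep = sd_x > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"zero-variance predictors excluded: {dropped}", RuntimeWarning)
    eta_c = eta - eta.mean()
    Xc = Xd - Xd.mean(axis=0)
    cov_xeta = (Xc * eta_c[:, None]).mean(axis=0)
    beta_nonint = fit.params.reindex(cols).to_numpy()
    std_beta = beta_nonint[keep] * sd_x[keep] / sd_latent
    corr = cov_xeta[keep] / (sd_x[keep] * sd_latent)
    kept_cols = [c for c, k in zip(cols, keep) if k]
    return pd.Series(std_beta, index=kept_cols), pd.Series(corr, index=kept_cols)
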