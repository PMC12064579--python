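"""Three-level random-effects meta-regression for standardized mean differences.

Effect sizes d_ij (effect i in sample j) follow

    d_ij = x_ij' γ + v_j + e_ij + ε_ij,
    v_j ~ N(0, τ²₃),  e_ij ~ N(0, τ²₂),  ε_ij ~ N(0, σ²_ij),

with known participant sampling variances σ²_ij (level 1), effect-level
heterogeneity τ²₂ (level 2), and sample-level heterogeneity τ²₃ (level 3).
Estimation profiles γ out by GLS and maximizes the (restricted) likelihood
over (τ²₂, τ²₃) with a bounded quasi-Newton search; the compound-symmetric
within-sample covariance V_j = diag(σ² + τ²₂) + τ²₃ 11' is handled in
closed form (Sherman–Morrison), so no dense matrix is ever built.

The intercept-only model yields the variance decomposition: total variance
= typical σ² + τ²₂ + τ²₃, with the level-1 "typical" sampling variance in
the Higgins–Thompson sense.  Level-wise explained variance of a moderator
model follows Cheung's proportional-reduction form
R²_ℓ = 1 − τ²_ℓ(model)/τ²_ℓ(null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import CodedMatrix
from .marginals import MarginalEstimate

INTERCEPT = "(Intercept)"


class Meta3Error(RuntimeError):
    pass


@dataclass
class Meta3Fit:
    """REML/ML fit of the 3-level meta-regression."""

    names: list[str]
    gamma: np.ndarray
    se: np.ndarray
    tau2_level2: float
    tau2_level3: float
    loglik: float
    method: str
    converged: bool
    n_effects: int
    n_samples: int
    vcov: np.ndarray
    columns_by_variable: dict = field(default_factory=dict)

    @property
    def mu(self) -> float:
        """Pooled effect (intercept); the model-implied grand mean at the
        reference categories."""
        return float(self.gamma[self.names.index(INTERCEPT)])

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.gamma, index=self.names)

    @property
    def coef(self) -> pd.Series:
        return self.params.drop(INTERCEPT)

    def wald_test(self, columns: Sequence[str]) -> tuple[float, int, float]:
        idx = [self.names.index(c) for c in columns]
        b = self.gamma[idx]
        V = self.vcov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return stat, len(idx), float(stats.chi2.sf(stat, len(idx)))

    @property
    def variable_p(self) -> dict[str, float]:
        return {
            var: self.wald_test(cols)[2]
            for var, cols in self.columns_by_variable.items()
            if cols
        }

    def summary(self) -> pd.DataFrame:
        z = self.gamma / self.se
        return pd.DataFrame(
            {"coef": self.gamma, "se": self.se, "z": z,
             "p": 2 * stats.norm.sf(np.abs(z))},
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {n: float(g) for n, g in zip(self.names, self.gamma)},
            "se": {n: float(s) for n, s in zip(self.names, self.se)},
            "tau2_level2": float(self.tau2_level2),
            "tau2_level3": float(self.tau2_level3),
            "loglik": float(self.loglik),
            "method": self.method,
            "converged": bool(self.converged),
            "n_effects": int(self.n_effects),
            "n_samples": int(self.n_samples),
        }


# ---------------------------------------------------------------------------
# likelihood in Sherman–Morrison form


def _prepare(cluster: np.ndarray):
    codes, uniq = pd.factorize(cluster)
    return codes.astype(np.int64), len(uniq)


def _gls_pieces(X, y, sigma2, codes, nclus, tau2, tau3):
    """X'V⁻¹X, X'V⁻¹y, y'V⁻¹y and log|V| for block compound symmetry."""
    d = sigma2 + tau2
    a = 1.0 / d
    S = np.bincount(codes, weights=a, minlength=nclus)
    c = tau3 / (1.0 + tau3 * S)
    aX = X * a[:, None]
    ay = y * a
    # per-cluster sums of a-weighted rows
    TX = np.zeros((nclus, X.shape[1]))
    np.add.at(TX, codes, aX)
    Ty = np.bincount(codes, weights=ay, minlength=nclus)
    XtVX = X.T @ aX - (TX * c[:, None]).T @ TX
    XtVy = X.T @ ay - TX.T @ (c * Ty)
    ytVy = float(y @ ay - Ty @ (c * Ty))
    logdet = float(np.sum(np.log(d)) + np.sum(np.log1p(tau3 * S)))
    return XtVX, XtVy, ytVy, logdet


def meta3_loglik(
    y: np.ndarray,
    sigma2: np.ndarray,
    X: np.ndarray,
    cluster: np.ndarray,
    tau2: float,
    tau3: float,
    method: str = "REML",
) -> float:
    """Profile (restricted) log-likelihood at (τ²₂, τ²₃), γ profiled by GLS.

    Exposed for oracle testing against dense-matrix evaluation and grid
    search.
    """
    codes, nclus = _prepare(cluster)
    n, p = X.shape
    XtVX, XtVy, ytVy, logdet = _gls_pieces(X, y, sigma2, codes, nclus, tau2, tau3)
    try:
        gamma = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf
    rss = ytVy - XtVy @ gamma
    rss = max(rss, 0.0)
    if method.upper() == "REML":
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_xvx + rss)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + rss)


def fit_meta3(
    y: np.ndarray,
    sampling_var: np.ndarray,
    X: Optional[pd.DataFrame],
    cluster: np.ndarray,
    method: str = "REML",
    fix_tau2: Optional[float] = None,
    fix_tau3: Optional[float] = None,
    columns_by_variable: Optional[dict] = None,
) -> Meta3Fit:
    """Fit the 3-level meta-regression.

    ``X`` holds the moderator dummy columns (or None for intercept-only);
    an intercept is always prepended.  ``fix_tau2``/``fix_tau3`` pin a
    variance component (e.g. ``fix_tau3=0`` reduces the model to an
    ordinary 2-level random-effects meta-analysis).  Negative variance
    proposals are excluded by box constraints; estimates on the boundary
    are reported as exactly 0.
    """
    y = np.asarray(y, dtype=float)
    sigma2 = np.asarray(sampling_var, dtype=float)
    if np.any(sigma2 <= 0):
        raise Meta3Error("all sampling variances must be > 0")
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        Xm = np.ones((len(y), 1))
        names = [INTERCEPT]
    else:
        Xm = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
        names = [INTERCEPT] + list(X.columns)
    codes, nclus = _prepare(cluster)
    if nclus < 2:
        raise Meta3Error("need at least 2 clusters")

    var_y = max(float(np.var(y)), 1e-6)
    ub = 10.0 * var_y

    free = []
    if fix_tau2 is None:
        free.append("tau2")
    if fix_tau3 is None:
        free.append("tau3")

    def unpack(theta):
        it = iter(theta)
        t2 = next(it) if fix_tau2 is None else fix_tau2
        t3 = next(it) if fix_tau3 is None else fix_tau3
        return t2, t3

    def negll(theta):
        t2, t3 = unpack(theta)
        return -meta3_loglik(y, sigma2, Xm, cluster, t2, t3, method)

    best = None
    if free:
        starts = [
            [var_y / 4.0] * len(free),
            [var_y / 20.0] * len(free),
            [var_y] * len(free),
        ]
        bounds = [(0.0, ub)] * len(free)
        for x0 in starts:
            res = optimize.minimize(
                negll, np.asarray(x0), method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        tau2, tau3 = unpack(best.x)
        converged = bool(best.success)
        loglik = -float(best.fun)
    else:
        tau2, tau3 = fix_tau2, fix_tau3
        converged = True
        loglik = -negll([])

    tau2 = max(float(tau2), 0.0)
    tau3 = max(float(tau3), 0.0)
    XtVX, XtVy, _, _ = _gls_pieces(Xm, y, sigma2, codes, nclus, tau2, tau3)
    vcov = np.linalg.inv(XtVX)
    gamma = vcov @ XtVy
    se = np.sqrt(np.diag(vcov))
    return Meta3Fit(
        names=names,
        gamma=gamma,
        se=se,
        tau2_level2=tau2,
        tau2_level3=tau3,
        loglik=loglik,
        method=method.upper(),
        converged=converged,
        n_effects=len(y),
        n_samples=nclus,
        vcov=vcov,
        columns_by_variable=dict(columns_by_variable or {}),
    )


def fit_meta3_coded(data: CodedMatrix, method: str = "REML", **kw) -> Meta3Fit:
    """Convenience wrapper taking a :class:`CodedMatrix` (meta path)."""
    if data.y is None or data.sampling_var is None:
        raise Meta3Error("CodedMatrix must carry d_abs response and sampling variances")
    return fit_meta3(
        data.y, data.sampling_var, data.X if data.X.shape[1] else None,
        data.cluster, method=method, columns_by_variable=data.columns_by_variable,
        **kw,
    )


# ---------------------------------------------------------------------------
# variance decomposition and level-wise R²


@dataclass
class VarianceDecomposition:
    total: float
    share_level1: float
    share_level2: float
    share_level3: float
    typical_sampling_var: float
    tau2_level2: float
    tau2_level3: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def typical_sampling_variance(sampling_var: np.ndarray) -> float:
    """Higgins–Thompson 'typical' within-study variance.

    s² = (k−1) Σw_i / ((Σw_i)² − Σw_i²) with w_i = 1/σ²_i — the summary
    level-1 variance used when expressing heterogeneity as proportions.
    """
    w = 1.0 / np.asarray(sampling_var, dtype=float)
    k = len(w)
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def decompose_variance(fit: Meta3Fit, sampling_var: np.ndarray) -> VarianceDecomposition:
    """Split total variance of effects into participant/effect/sample levels.

    Intended for an intercept-only (null) fit: total = typical σ² + τ²₂ +
    τ²₃ and each share is its component over the total.
    """
    s2 = typical_sampling_variance(sampling_var)
    total = s2 + fit.tau2_level2 + fit.tau2_level3
    return VarianceDecomposition(
        total=total,
        share_level1=s2 / total,
        share_level2=fit.tau2_level2 / total,
        share_level3=fit.tau2_level3 / total,
        typical_sampling_var=s2,
        tau2_level2=fit.tau2_level2,
        tau2_level3=fit.tau2_level3,
    )


def r2_by_level(fit_null: Meta3Fit, fit_full: Meta3Fit) -> tuple[Optional[float], Optional[float]]:
    """Cheung's proportional reduction in heterogeneity per level.

    R²_ℓ = max(0, 1 − τ²_ℓ(full)/τ²_ℓ(null)); None when the null variance at
    that level is zero (undefined).
    """
    if fit_null.n_effects != fit_full.n_effects:
        raise Meta3Error("null and full fits must use the same data")
    out = []
    for t_null, t_full in [
        (fit_null.tau2_level2, fit_full.tau2_level2),
        (fit_null.tau2_level3, fit_full.tau2_level3),
    ]:
        out.append(max(0.0, 1.0 - t_full / t_null) if t_null > 0 else None)
    return out[0], out[1]


def marginal_mean_es(
    fit: Meta3Fit, data: CodedMatrix, variable: str, category: str
) -> MarginalEstimate:
    """Marginal-standardized mean effect size for one category.

    The mean function is linear, so this equals the adjusted mean with
    ``variable`` set to ``category`` for every row and the other covariates
    averaged over their observed distribution.
    """
    from .marginals import _design_with_category

    X = _design_with_category(data, variable, category)
    gamma = fit.params.reindex([INTERCEPT] + list(data.X.columns), fill_value=0.0).to_numpy()
    est = float(np.mean(gamma[0] + X @ gamma[1:]))
    return MarginalEstimate(variable=variable, category=category, estimate=est)
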