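"""Marginal standardization, cluster bootstrap CIs, and Pratt-index shares.

*Marginal standardization* turns a fitted (possibly multilevel) regression
into population-level adjusted estimates: fix one covariate at a category
for every observation, keep all other covariates at their observed values,
and average the model predictions.  For the logistic detection model the
default prediction is population-averaged — the inverse-logit is integrated
over the random-intercept distribution N(0, τ̂²) by Gauss–Hermite quadrature
— with cluster-conditional (u = 0) predictions available as an option.

Confidence intervals come from the *cluster bootstrap*: sample ids are
resampled with replacement (all effects of a drawn sample enter once per
draw, under a fresh cluster label), the statistic is recomputed per
replicate, and percentile intervals are reported.

The *Pratt index* partitions a model's explained variance over predictors:
share_j = (standardized β̂_j · r_j) / R², where r_j is the predictor–response
correlation.  Shares of a categorical variable sum over its dummies; negative
shares can arise under suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import CodedMatrix
from .glmm import GlmmFit


class MarginalsError(ValueError):
    pass


@dataclass
class MarginalEstimate:
    """Marginal-standardized probability or mean for one category."""

    variable: str
    category: str
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_effects: Optional[int] = None
    n_samples: Optional[int] = None
    n_studies: Optional[int] = None


def _design_with_category(
    data: CodedMatrix, variable: str, category: str
) -> np.ndarray:
    if variable not in data.variables:
        raise MarginalsError(f"unknown variable '{variable}'")
    if category not in data.variables[variable]:
        raise MarginalsError(
            f"unknown category '{category}' for variable '{variable}' "
            f"(declared: {data.variables[variable]})"
        )
    X = data.X.to_numpy(dtype=float).copy()
    cols = list(data.X.columns)
    for col in data.columns_by_variable[variable]:
        j = cols.index(col)
        X[:, j] = 1.0 if col == f"{variable}:{category}" else 0.0
    return X


def population_averaged_probability(
    eta: np.ndarray, tau2: float, nq: int = 31
) -> np.ndarray:
    """E_u[expit(eta + u)] with u ~ N(0, τ²), by Gauss–Hermite quadrature."""
    if tau2 <= 0:
        return expit(eta)
    z, w = np.polynomial.hermite.hermgauss(nq)
    u = np.sqrt(2.0 * tau2) * z
    probs = expit(eta[:, None] + u[None, :])
    return probs @ (w / np.sqrt(np.pi))


def marginal_standardize(
    fit: GlmmFit,
    data: CodedMatrix,
    variable: str,
    category: str,
    population_averaged: bool = True,
) -> MarginalEstimate:
    """Marginal-standardized detection probability for one category.

    Every row's ``variable`` is set to ``category`` (other covariates stay at
    observed values) and model-predicted probabilities are averaged.  With
    ``population_averaged`` (default) predictions integrate over the random
    intercept; otherwise they condition on u = 0 (cluster-median sample).
    """
    X = _design_with_category(data, variable, category)
    beta = fit.params.reindex(["(Intercept)"] + list(data.X.columns), fill_value=0.0).to_numpy()
    eta = beta[0] + X @ beta[1:]
    if population_averaged:
        p = population_averaged_probability(eta, fit.tau2)
    else:
        p = expit(eta)
    return MarginalEstimate(variable=variable, category=category, estimate=float(p.mean()))


def overall_marginal_probability(
    fit: GlmmFit, data: CodedMatrix, population_averaged: bool = True
) -> float:
    """Average model-predicted probability at observed covariates."""
    X = data.X.to_numpy(dtype=float)
    beta = fit.params.reindex(["(Intercept)"] + list(data.X.columns), fill_value=0.0).to_numpy()
    eta = beta[0] + X @ beta[1:]
    p = population_averaged_probability(eta, fit.tau2) if population_averaged else expit(eta)
    return float(p.mean())


# ---------------------------------------------------------------------------
# cluster bootstrap


@dataclass
class ClusterBootstrapResult:
    ci_low: np.ndarray
    ci_high: np.ndarray
    draws: np.ndarray  # (B_successful, k)
    n_failed: int

    def scalar_ci(self) -> tuple[float, float]:
        return float(self.ci_low[0]), float(self.ci_high[0])


def resample_clusters(
    effects: pd.DataFrame, rng: np.random.Generator, cluster_col: str = "sample_id"
) -> pd.DataFrame:
    """One cluster-bootstrap replicate: sample ids drawn with replacement.

    A sample drawn twice contributes all its effects twice, under distinct
    relabeled cluster ids so downstream fits treat the copies as independent
    clusters (standard cluster-bootstrap convention).
    """
    ids = effects[cluster_col].unique()
    drawn = rng.choice(ids, size=len(ids), replace=True)
    groups = dict(tuple(effects.groupby(cluster_col, sort=False)))
    parts = []
    for r, sid in enumerate(drawn):
        g = groups[sid].copy()
        g[cluster_col] = f"{sid}#{r}"
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def cluster_bootstrap(
    effects: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], object],
    B: int,
    seed: int,
    cluster_col: str = "sample_id",
    ci_level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> ClusterBootstrapResult:
    """Percentile cluster-bootstrap CI of ``statistic(effects)``.

    ``statistic`` returns a scalar or 1-d array; failing replicates are
    dropped and counted, with an error if more than ``max_failure_rate`` of
    the B replicates fail.  Deterministic given ``seed``  (PCG64 generator).
    """
    if B < 2:
        raise MarginalsError("B must be >= 2")
    if effects[cluster_col].nunique() < 2:
        raise MarginalsError("need at least 2 clusters to bootstrap")
    rng = np.random.default_rng(seed)
    # index clusters once; replicates are cheap positional takes
    codes, uniq = pd.factorize(effects[cluster_col])
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(uniq)))
    ends = np.append(starts[1:], len(sorted_codes))
    cluster_rows = [order[s:e] for s, e in zip(starts, ends)]

    def _replicate() -> pd.DataFrame:
        drawn = rng.integers(0, len(uniq), size=len(uniq))
        rows = np.concatenate([cluster_rows[j] for j in drawn])
        rep = effects.iloc[rows].copy()
        rep[cluster_col] = np.repeat(
            [f"{uniq[j]}#{r}" for r, j in enumerate(drawn)],
            [len(cluster_rows[j]) for j in drawn],
        )
        return rep.reset_index(drop=True)

    draws = []
    n_failed = 0
    for _ in range(B):
        rep = _replicate()
        try:
            val = np.atleast_1d(np.asarray(statistic(rep), dtype=float))
            if np.any(~np.isfinite(val)):
                raise FloatingPointError("non-finite statistic")
            draws.append(val)
        except Exception:
            n_failed += 1
    if n_failed > max_failure_rate * B:
        raise MarginalsError(
            f"{n_failed}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )
    arr = np.vstack(draws)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(arr, alpha, axis=0)
    hi = np.quantile(arr, 1.0 - alpha, axis=0)
    return ClusterBootstrapResult(ci_low=lo, ci_high=hi, draws=arr, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Pratt-index partition of explained variance


@dataclass
class PrattShare:
    """Share of explained variance attributable to one variable.

    Negative shares may indicate variable suppression (or rounding of the
    inputs); they are reported as-is.
    """

    variable: str
    share: float
    component_shares: dict = field(default_factory=dict)


def pratt_index(
    standardized_betas: pd.Series,
    correlations: pd.Series,
    r2: float,
    columns_by_variable: Optional[dict[str, Sequence[str]]] = None,
) -> list[PrattShare]:
    """Pratt partition: share_j = std β̂_j · r_j / R², summed per variable.

    With ``columns_by_variable`` the per-dummy shares are aggregated to
    whole-variable shares; otherwise each column is its own variable.
    """
    if r2 <= 0:
        raise MarginalsError("Pratt index undefined for R² <= 0")
    per_dummy = (standardized_betas * correlations.reindex(standardized_betas.index)) / r2
    if columns_by_variable is None:
        columns_by_variable = {c: [c] for c in per_dummy.index}
    out = []
    for var, cols in columns_by_variable.items():
        cols = [c for c in cols if c in per_dummy.index]
        if not cols:
            continue
        comp = {c: float(per_dummy[c]) for c in cols}
        out.append(PrattShare(variable=var, share=float(sum(comp.values())),
                              component_shares=comp))
    return out
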