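"""End-to-end analysis arms: detection (2-level logistic) and magnitude
(3-level meta-regression), with report tables.

Each arm runs the same skeleton the analysis plan prescribes: overlap
exclusion → covariate coding → purposeful selection of explanatory
variables → forced addition of study-quality controls → final model →
marginal standardization with cluster-bootstrap CIs → explained-variance
accounting (latent R² + Pratt shares for detection; level-wise R² + variance
decomposition for magnitude).  Every number in the emitted tables is a
serialized intermediate of these stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from . import glmm as gl
from . import marginals as mg
from . import meta3 as m3
from .selection import SelectionConfig, SelectionTrace, purposeful_select
from .synthetic import GeneratorConfig

logger = logging.getLogger("rsmeta")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def variables_from_generator(config: GeneratorConfig) -> dict[str, list[str]]:
    """Variable → category map implied by a generator configuration."""
    return {c.name: list(c.categories) for c in config.covariate_spec}


def infer_variables(
    effects: pd.DataFrame, columns: Sequence[str]
) -> dict[str, list[str]]:
    """Infer category sets from data; the modal category becomes reference."""
    out = {}
    for col in columns:
        counts = effects[col].value_counts()
        out[col] = [str(c) for c in counts.index]
    return out


def _category_counts(effects: pd.DataFrame, variable: str, category: str) -> dict:
    sub = effects[effects[variable].astype(object) == category]
    return {
        "n_effects": int(len(sub)),
        "n_samples": int(sub["sample_id"].nunique()),
        "n_studies": int(sub["study_id"].nunique()) if "study_id" in sub else None,
    }


# ---------------------------------------------------------------------------
# family adapters for the selection engine


def make_glmm_fit_fn(
    effects: pd.DataFrame,
    variables: dict[str, list[str]],
    response: str = "detected",
    spec: Optional[gl.GlmmSpec] = None,
):
    """fit_fn over the 2-level logistic family for purposeful selection."""

    def fit_fn(subset: Sequence[str]):
        coded = ds.code_design_matrix(
            effects, {v: variables[v] for v in subset}, response=response
        )
        return gl.fit_glmm(coded, spec)

    return fit_fn


class _PlainLogisticFit:
    """Adapter exposing the selection-engine interface for a GLM logistic fit."""

    def __init__(self, res, columns_by_variable):
        self._res = res
        self.columns_by_variable = columns_by_variable

    @property
    def coef(self) -> pd.Series:
        return self._res.params.drop("(Intercept)", errors="ignore")

    @property
    def variable_p(self) -> dict[str, float]:
        out = {}
        for var, cols in self.columns_by_variable.items():
            if cols:
                constraint = ", ".join(f"{c} = 0" for c in cols)
                out[var] = float(self._res.wald_test(constraint, scalar=True).pvalue)
        return out


def make_plain_logistic_fit_fn(
    effects: pd.DataFrame,
    variables: dict[str, list[str]],
    response: str = "detected",
):
    """fit_fn over ordinary (non-clustered) logistic regression.

    A lightweight family for the selection engine when clustering is absent
    or ignorable; estimation is delegated to statsmodels GLM/binomial.
    """
    import statsmodels.api as sm

    def fit_fn(subset: Sequence[str]):
        coded = ds.code_design_matrix(
            effects, {v: variables[v] for v in subset}, response=response
        )
        X = coded.X.copy()
        X.insert(0, "(Intercept)", 1.0)
        res = sm.GLM(coded.y, X, family=sm.families.Binomial()).fit()
        return _PlainLogisticFit(res, coded.columns_by_variable)

    return fit_fn


def make_meta3_fit_fn(
    effects: pd.DataFrame,
    variables: dict[str, list[str]],
    method: str = "REML",
):
    """fit_fn over the 3-level meta-regression family."""

    def fit_fn(subset: Sequence[str]):
        coded = ds.code_design_matrix(
            effects, {v: variables[v] for v in subset},
            response="d_abs", sampling_var="sampling_var",
        )
        return m3.fit_meta3_coded(coded, method=method)

    return fit_fn


# ---------------------------------------------------------------------------
# detection arm


@dataclass
class DetectionReport:
    counts: dict
    trace: SelectionTrace
    null_fit: gl.GlmmFit
    final_fit: gl.GlmmFit
    r2: gl.VarianceExplained
    table: pd.DataFrame
    pratt: list[mg.PrattShare]
    overall: mg.MarginalEstimate

    def partition(self) -> dict:
        """Explained-variance partition (pie-chart style) as percentages."""
        return {
            "r2_total": self.r2.r2_total,
            "r2_effect_level": self.r2.r2_effect,
            "r2_sample_level": self.r2.r2_sample,
            "pratt_percent_of_r2": {p.variable: 100.0 * p.share for p in self.pratt},
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "detection_table.csv", index=False)
        (outdir / "detection_partition.json").write_text(
            json.dumps(self.partition(), indent=2)
        )
        (outdir / "detection_selection_trace.json").write_text(self.trace.to_json())
        (outdir / "detection_fit.json").write_text(
            json.dumps(
                {"final": self.final_fit.to_dict(), "null": self.null_fit.to_dict(),
                 "r2": self.r2.to_dict(), "counts": self.counts},
                indent=2,
            )
        )


@_stage("detection")
def run_detection_arm(
    effects: pd.DataFrame,
    variables: dict[str, list[str]],
    candidates: Sequence[str],
    forced_controls: Sequence[str] = (),
    selection: Optional[SelectionConfig] = None,
    bootstrap_B: int = 1000,
    seed: Optional[int] = None,
    glmm_spec: Optional[gl.GlmmSpec] = None,
    population_averaged: bool = True,
) -> DetectionReport:
    """Full detection arm on an effect table with a binary ``detected`` column.

    ``seed`` is required whenever ``bootstrap_B > 0`` (no silent seeding).
    """
    if bootstrap_B > 0 and seed is None:
        raise PipelineError("[detection] bootstrap requires an explicit seed")

    included, excluded, excl_counts = ds.exclude_overlapping(effects)
    counts = {
        "n_effects": int(len(included)),
        "n_samples": int(included["sample_id"].nunique()),
        "n_studies": int(included["study_id"].nunique()) if "study_id" in included else None,
        "n_detected": int(included["detected"].sum()),
        **excl_counts,
    }
    logger.info("detection: %(n_effects)d effects from %(n_samples)d samples "
                "(%(effects_excluded)d excluded)", counts)

    fit_fn = make_glmm_fit_fn(included, variables, spec=glmm_spec)
    sel_cfg = selection or SelectionConfig(
        candidates=list(candidates), forced_controls=list(forced_controls)
    )
    final_fit, trace = purposeful_select(sel_cfg, fit_fn)
    logger.info("detection: final variables %s + forced %s",
                trace.final_variables, trace.forced_added)

    model_vars = trace.final_variables + trace.forced_added
    coded = ds.code_design_matrix(
        included, {v: variables[v] for v in model_vars}, response="detected"
    )
    null_fit = fit_fn([])
    r2 = gl.latent_r2(null_fit, final_fit, coded)
    std_beta, corr = gl.standardized_solution(final_fit, coded)
    pratt = (
        mg.pratt_index(std_beta, corr, r2.r2_total, coded.columns_by_variable)
        if r2.r2_total > 0
        else []
    )

    # marginal estimates: overall + every category of every model variable
    cells: list[tuple[str, str]] = [("overall", "overall")]
    for v in model_vars:
        cells += [(v, c) for c in coded.variables[v]]

    def _all_marginals(df: pd.DataFrame, warm=None) -> np.ndarray:
        cd = ds.code_design_matrix(
            df, {v: variables[v] for v in model_vars}, response="detected"
        )
        start = warm if warm is not None else None
        fit = gl.fit_glmm(cd, glmm_spec, start=start)
        vals = [mg.overall_marginal_probability(fit, cd, population_averaged)]
        for v, c in cells[1:]:
            vals.append(
                mg.marginal_standardize(fit, cd, v, c, population_averaged).estimate
            )
        return np.asarray(vals)

    point = _all_marginals(included)
    if bootstrap_B > 0:
        warm = np.append(final_fit.beta, np.sqrt(final_fit.tau2))
        boot = mg.cluster_bootstrap(
            included, lambda df: _all_marginals(df, warm), bootstrap_B, seed
        )
        lo, hi = boot.ci_low, boot.ci_high
    else:
        lo = hi = np.full(len(cells), np.nan)

    pratt_by_var = {p.variable: 100.0 * p.share for p in pratt}
    rows = []
    for k, (v, c) in enumerate(cells):
        cc = (
            _category_counts(included, v, c)
            if v != "overall"
            else {"n_effects": counts["n_effects"], "n_samples": counts["n_samples"],
                  "n_studies": counts["n_studies"]}
        )
        is_ref = v != "overall" and c == coded.reference[v]
        rows.append(
            {
                "variable": v,
                "category": c,
                **cc,
                "marginal_probability": point[k],
                "ci_low": lo[k],
                "ci_high": hi[k],
                # whole-variable Pratt share, shown on non-reference rows
                "pratt_percent_r2": np.nan
                if (v == "overall" or is_ref)
                else pratt_by_var.get(v, np.nan),
            }
        )
    table = pd.DataFrame(rows)

    overall = mg.MarginalEstimate(
        variable="overall", category="overall", estimate=float(point[0]),
        ci_low=float(lo[0]) if np.isfinite(lo[0]) else None,
        ci_high=float(hi[0]) if np.isfinite(hi[0]) else None,
        n_effects=counts["n_effects"], n_samples=counts["n_samples"],
        n_studies=counts["n_studies"],
    )
    return DetectionReport(
        counts=counts, trace=trace, null_fit=null_fit, final_fit=final_fit,
        r2=r2, table=table, pratt=pratt, overall=overall,
    )


# ---------------------------------------------------------------------------
# magnitude arm


@dataclass
class MagnitudeReport:
    counts: dict
    trace: SelectionTrace
    null_fit: m3.Meta3Fit
    final_fit: m3.Meta3Fit
    decomposition: m3.VarianceDecomposition
    r2_level2: Optional[float]
    r2_level3: Optional[float]
    table: pd.DataFrame
    overall: mg.MarginalEstimate

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "magnitude_table.csv", index=False)
        (outdir / "magnitude_selection_trace.json").write_text(self.trace.to_json())
        (outdir / "magnitude_fit.json").write_text(
            json.dumps(
                {
                    "final": self.final_fit.to_dict(),
                    "null": self.null_fit.to_dict(),
                    "variance_decomposition": self.decomposition.to_dict(),
                    "r2_level2": self.r2_level2,
                    "r2_level3": self.r2_level3,
                    "counts": self.counts,
                },
                indent=2,
            )
        )


@_stage("magnitude")
def run_magnitude_arm(
    effects: pd.DataFrame,
    variables: dict[str, list[str]],
    candidates: Sequence[str],
    forced_controls: Sequence[str] = (),
    selection: Optional[SelectionConfig] = None,
    bootstrap_B: int = 1000,
    seed: Optional[int] = None,
    method: str = "REML",
    es_methods: Optional[Sequence[str]] = None,
) -> MagnitudeReport:
    """Full magnitude arm on an effect table with d_abs + sampling_var.

    ``es_methods`` optionally restricts to effects whose ``rs_method`` allows
    a standardized mean difference (e.g. then-test and SEM).
    """
    if bootstrap_B > 0 and seed is None:
        raise PipelineError("[magnitude] bootstrap requires an explicit seed")

    included, excluded, excl_counts = ds.exclude_overlapping(effects)
    if es_methods is not None and "rs_method" in included.columns:
        included = included[included["rs_method"].isin(es_methods)]
    if "d_abs" not in included.columns or "sampling_var" not in included.columns:
        raise PipelineError("[magnitude] effect table lacks d_abs/sampling_var columns")
    estimable = included["d_abs"].notna() & included["sampling_var"].notna()
    if not estimable.any():
        bad = included["effect_id"].tolist()
        raise PipelineError(
            f"[magnitude] no estimable effect sizes; inestimable effects: {bad[:20]}"
            + ("..." if len(bad) > 20 else "")
        )
    included = included[estimable].copy()
    counts = {
        "n_effects": int(len(included)),
        "n_samples": int(included["sample_id"].nunique()),
        "n_studies": int(included["study_id"].nunique()) if "study_id" in included else None,
        "n_inestimable": int((~estimable).sum()),
        **excl_counts,
    }
    logger.info("magnitude: %(n_effects)d estimable effects from %(n_samples)d samples",
                counts)

    fit_fn = make_meta3_fit_fn(included, variables, method=method)
    sel_cfg = selection or SelectionConfig(
        candidates=list(candidates), forced_controls=list(forced_controls)
    )
    final_fit, trace = purposeful_select(sel_cfg, fit_fn)
    model_vars = trace.final_variables + trace.forced_added
    coded = ds.code_design_matrix(
        included, {v: variables[v] for v in model_vars},
        response="d_abs", sampling_var="sampling_var",
    )
    null_fit = fit_fn([])
    decomposition = m3.decompose_variance(null_fit, included["sampling_var"].to_numpy())
    r2_l2, r2_l3 = m3.r2_by_level(null_fit, final_fit)

    cells: list[tuple[str, str]] = [("overall", "overall")]
    for v in model_vars:
        cells += [(v, c) for c in coded.variables[v]]

    def _all_means(df: pd.DataFrame) -> np.ndarray:
        cd = ds.code_design_matrix(
            df, {v: variables[v] for v in model_vars},
            response="d_abs", sampling_var="sampling_var",
        )
        fit = m3.fit_meta3_coded(cd, method=method)
        X = cd.X.to_numpy(dtype=float)
        gam = fit.params.reindex([m3.INTERCEPT] + list(cd.X.columns)).to_numpy()
        vals = [float(np.mean(gam[0] + X @ gam[1:]))]
        for v, c in cells[1:]:
            vals.append(m3.marginal_mean_es(fit, cd, v, c).estimate)
        return np.asarray(vals)

    point = _all_means(included)
    if bootstrap_B > 0:
        boot = mg.cluster_bootstrap(included, _all_means, bootstrap_B, seed)
        lo, hi = boot.ci_low, boot.ci_high
    else:
        lo = hi = np.full(len(cells), np.nan)

    rows = []
    for k, (v, c) in enumerate(cells):
        cc = (
            _category_counts(included, v, c)
            if v != "overall"
            else {"n_effects": counts["n_effects"], "n_samples": counts["n_samples"],
                  "n_studies": counts["n_studies"]}
        )
        rows.append(
            {"variable": v, "category": c, **cc,
             "marginal_mean_es": point[k], "ci_low": lo[k], "ci_high": hi[k]}
        )
    table = pd.DataFrame(rows)

    overall = mg.MarginalEstimate(
        variable="overall", category="overall", estimate=float(point[0]),
        ci_low=float(lo[0]) if np.isfinite(lo[0]) else None,
        ci_high=float(hi[0]) if np.isfinite(hi[0]) else None,
        n_effects=counts["n_effects"], n_samples=counts["n_samples"],
        n_studies=counts["n_studies"],
    )
    return MagnitudeReport(
        counts=counts, trace=trace, null_fit=null_fit, final_fit=final_fit,
        decomposition=decomposition, r2_level2=r2_l2, r2_level3=r2_l3,
        table=table, overall=overall,
    )
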