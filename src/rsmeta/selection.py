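"""Hosmer–Lemeshow purposeful variable selection, generic over model family.

The engine drives any fit function that, given a list of candidate
variables, returns a fit exposing (a) a joint p-value per variable block
(``variable_p``) and (b) coefficients keyed by dummy column (``coef``).
Both analysis arms plug in here: the 2-level logistic detection model and
the 3-level meta-regression for effect sizes.

Steps:

1. univariate screening — variables with a univariate p below
   ``alpha_screen`` (default 0.25, deliberately liberal) enter the
   multivariable model;
2. iterative backward pruning — the least-significant variable with
   p ≥ ``alpha_retain`` (default 0.10) is removed *unless* removing it is
   confounding, i.e. changes any remaining coefficient by more than
   ``confounding_threshold`` (default 20%) relative to the fuller model;
   repeat until every retained variable is significant or a confounder;
3. re-entry — each variable screened out in step 1 is re-tested in the
   step-2 model and retained if p < ``alpha_retain``.

Control variables in ``forced_controls`` are appended to the final model
without selection.  Multi-category variables enter and leave as whole blocks
(joint Wald test of their dummies).  The procedure is deterministic given
the data and the candidate ordering; ties in removal order break toward the
highest p-value first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd


class SelectionError(RuntimeError):
    """Raised when a model fit fails mid-procedure; carries the trace so far."""

    def __init__(self, message: str, trace: "SelectionTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class SelectionConfig:
    alpha_screen: float = 0.25
    alpha_retain: float = 0.10
    confounding_threshold: float = 0.20
    candidates: list[str] = field(default_factory=list)
    forced_controls: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 < self.alpha_retain <= self.alpha_screen < 1.0):
            raise ValueError(
                "require 0 < alpha_retain <= alpha_screen < 1, got "
                f"{self.alpha_retain}, {self.alpha_screen}"
            )
        if self.confounding_threshold <= 0:
            raise ValueError("confounding_threshold must be > 0")


@dataclass
class SelectionTrace:
    """Audit log of the purposeful-selection run."""

    step1_pvalues: dict = field(default_factory=dict)
    screened_in: list = field(default_factory=list)
    screened_out: list = field(default_factory=list)
    removals: list = field(default_factory=list)       # (variable, p, reason)
    kept_confounders: list = field(default_factory=list)  # (variable, p, changed_terms)
    reentries: list = field(default_factory=list)      # (variable, p)
    final_variables: list = field(default_factory=list)
    forced_added: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def log_lines(self) -> list[str]:
        lines = ["Step 1 (univariate screen):"]
        for v, p in self.step1_pvalues.items():
            mark = "in" if v in self.screened_in else "out"
            lines.append(f"  {v}: p={p:.4g} -> {mark}")
        lines.append("Step 2 (iterative removal):")
        for v, p, reason in self.removals:
            lines.append(f"  removed {v} (p={p:.4g}, {reason})")
        for v, p, terms in self.kept_confounders:
            lines.append(f"  kept {v} despite p={p:.4g}: confounder for {terms}")
        lines.append("Step 3 (re-entry):")
        for v, p in self.reentries:
            lines.append(f"  re-entered {v} (p={p:.4g})")
        lines.append(f"Final variables: {self.final_variables}")
        lines.append(f"Forced controls: {self.forced_added}")
        return lines


def confounding_check(
    full_coef: pd.Series,
    reduced_coef: pd.Series,
    threshold: float = 0.20,
    exclude: Sequence[str] = ("(Intercept)", "intercept"),
) -> tuple[float, list[str]]:
    """Relative coefficient change between a fuller and a reduced fit.

    For every coefficient the two fits share (intercept excluded), compute
    |Δβ| / |β_full| and flag those above ``threshold``.  If β_full = 0 for a
    shared term, the absolute change is compared against the threshold
    instead (documented fallback; a relative change is undefined there).
    """
    shared = [c for c in full_coef.index if c in reduced_coef.index and c not in exclude]
    max_change = 0.0
    flagged = []
    for c in shared:
        b_full, b_red = float(full_coef[c]), float(reduced_coef[c])
        denom = abs(b_full)
        change = abs(b_red - b_full) / denom if denom > 0 else abs(b_red - b_full)
        max_change = max(max_change, change)
        if change > threshold:
            flagged.append(c)
    return max_change, flagged


def purposeful_select(
    config: SelectionConfig,
    fit_fn: Callable[[Sequence[str]], object],
) -> tuple[object, SelectionTrace]:
    """Run purposeful selection; returns (final fit, trace).

    ``fit_fn(variables)`` must fit the model family on the given variable
    subset and return an object with ``variable_p`` (dict variable → joint
    p-value) and ``coef`` (pd.Series of non-intercept coefficients).
    """
    trace = SelectionTrace()

    def _fit(variables: Sequence[str], stage: str):
        try:
            return fit_fn(list(variables))
        except Exception as exc:  # abort with trace-so-far
            raise SelectionError(f"fit failed during {stage} on {list(variables)}: {exc}",
                                 trace) from exc

    # Step 1: univariate screening
    for var in config.candidates:
        fit = _fit([var], "step 1")
        p = fit.variable_p[var]
        trace.step1_pvalues[var] = float(p)
        (trace.screened_in if p < config.alpha_screen else trace.screened_out).append(var)

    current = list(trace.screened_in)

    # Step 2: iterative backward pruning with confounding protection
    fit = _fit(current, "step 2") if current else None
    while current:
        pvals = {v: fit.variable_p[v] for v in current}
        removable = sorted(
            (v for v in current if pvals[v] >= config.alpha_retain),
            key=lambda v: -pvals[v],
        )
        removed_this_round = False
        for v in removable:
            reduced_vars = [w for w in current if w != v]
            reduced = _fit(reduced_vars, "step 2") if reduced_vars else None
            if reduced is not None:
                _, flagged = confounding_check(
                    fit.coef, reduced.coef, config.confounding_threshold
                )
            else:
                flagged = []
            if flagged:
                trace.kept_confounders.append((v, float(pvals[v]), flagged))
                continue
            trace.removals.append((v, float(pvals[v]), "nonsignificant_nonconfounder"))
            current = reduced_vars
            fit = reduced
            removed_this_round = True
            break
        if not removed_this_round:
            break

    # Step 3: re-entry of screened-out variables
    for var in trace.screened_out:
        trial = _fit(current + [var], "step 3")
        p = trial.variable_p[var]
        if p < config.alpha_retain:
            trace.reentries.append((var, float(p)))
    current = current + [v for v, _ in trace.reentries]

    trace.final_variables = list(current)
    trace.forced_added = [v for v in config.forced_controls if v not in current]

    final_vars = current + trace.forced_added
    final_fit = _fit(final_vars, "final") if final_vars else _fit([], "final")
    return final_fit, trace
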