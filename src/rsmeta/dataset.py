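"""Data model, overlap exclusion, and covariate coding for effect tables.

The unit of analysis is a response-shift *effect*; effects are nested in
*samples* (unique participant groups), which is the clustering key throughout
— a sample may be analyzed in several studies, so study id is carried only
for reporting.  Two preparation steps precede any model fit:

1. overlap exclusion — when a study analyzed a subsample of a participant
   group whose overall sample is also in the data, the subsample's effects
   are dropped so no participant is counted twice;
2. reference-coded dummy expansion of the categorical covariates, with
   missing values mapped to an explicit "other/unknown" category rather than
   dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class DatasetValidationError(ValueError):
    pass


UNKNOWN_LABEL = "other_unknown"

#: Per-sample participant-count quartile cutpoints of the response-shift
#: corpus; Q1: n < 57, Q2: 57–254, Q3: 255–410, Q4: > 410.  Boundary values
#: fall in the lower bin.  Overridable / recomputable from data.
DEFAULT_SIZE_CUTPOINTS = (57, 254, 410)


@dataclass(frozen=True)
class EffectRecord:
    """One response-shift effect (typed view of an effect-table row)."""

    effect_id: str
    study_id: str
    sample_id: str
    detected: Optional[int] = None
    d_abs: Optional[float] = None
    sampling_var: Optional[float] = None
    is_subsample_of: Optional[str] = None
    covariates: dict = field(default_factory=dict)


def records_to_frame(records: Sequence[EffectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "effect_id": r.effect_id,
            "study_id": r.study_id,
            "sample_id": r.sample_id,
            "detected": r.detected,
            "d_abs": r.d_abs,
            "sampling_var": r.sampling_var,
            "is_subsample_of": r.is_subsample_of,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def load_effects(path) -> pd.DataFrame:
    """Read an effect table (one CSV row per effect)."""
    df = pd.read_csv(path)
    for col in ("effect_id", "study_id", "sample_id"):
        if col not in df.columns:
            raise DatasetValidationError(f"effect table missing required column '{col}'")
    return df


# ---------------------------------------------------------------------------
# overlap / subsample exclusion


def exclude_overlapping(effects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop effects from subsamples whose overall sample is also analyzed.

    A sample with an ``is_subsample_of`` link (possibly chained) pointing at
    any sample that has effects in the data is excluded.  Studies left with
    zero effects afterwards are dropped from the study count.

    Returns ``(included, excluded, counts)`` with counts of effects excluded,
    distinct subsamples involved, and studies dropped.
    """
    if "is_subsample_of" not in effects.columns:
        counts = {"effects_excluded": 0, "subsamples_excluded": 0, "studies_dropped": 0}
        return effects.copy(), effects.iloc[0:0].copy(), counts

    links = (
        effects.dropna(subset=["is_subsample_of"])
        .drop_duplicates("sample_id")
        .set_index("sample_id")["is_subsample_of"]
        .to_dict()
    )
    present = set(effects["sample_id"])

    def _walk(sample: str):
        """Yield the ancestor chain, raising on a cycle."""
        seen = {sample}
        cur = links.get(sample)
        while cur is not None and not (isinstance(cur, float) and np.isnan(cur)):
            if cur in seen:
                raise DatasetValidationError(
                    f"cyclic subsample links involving sample '{cur}'"
                )
            yield cur
            seen.add(cur)
            cur = links.get(cur)

    # validate the whole link graph before excluding anything
    for s in links:
        for _ in _walk(s):
            pass

    def ancestor_in_data(sample: str) -> bool:
        return any(a in present for a in _walk(sample))

    drop_samples = {s for s in links if ancestor_in_data(s)}
    mask = effects["sample_id"].isin(drop_samples)
    included, excluded = effects[~mask].copy(), effects[mask].copy()
    studies_dropped = len(set(effects["study_id"]) - set(included["study_id"]))
    counts = {
        "effects_excluded": int(mask.sum()),
        "subsamples_excluded": len(drop_samples),
        "studies_dropped": studies_dropped,
    }
    return included, excluded, counts


# ---------------------------------------------------------------------------
# sample-size quartiles


def sample_size_quartile(n, cutpoints=DEFAULT_SIZE_CUTPOINTS) -> np.ndarray:
    """Assign per-sample participant counts to quartile labels Q1..Q4.

    Values equal to a cutpoint fall in the lower bin (n = 57 → Q2 under the
    default cutpoints because Q2 is the closed range 57–254; n = 254 → Q2).
    """
    n = np.atleast_1d(np.asarray(n, dtype=float))
    c1, c2, c3 = cutpoints
    labels = np.empty(n.shape, dtype=object)
    labels[n < c1] = "Q1"
    labels[(n >= c1) & (n <= c2)] = "Q2"
    labels[(n > c2) & (n <= c3)] = "Q3"
    labels[n > c3] = "Q4"
    return labels


def compute_size_cutpoints(per_sample_n: Sequence[float]) -> tuple[float, float, float]:
    """Empirical quartile cutpoints of the per-sample participant counts."""
    q = np.quantile(np.asarray(per_sample_n, dtype=float), [0.25, 0.5, 0.75])
    return float(q[0]), float(q[1]), float(q[2])


def add_sample_size_quartile(
    effects: pd.DataFrame,
    sample_table: pd.DataFrame,
    cutpoints=DEFAULT_SIZE_CUTPOINTS,
    recompute: bool = False,
    column: str = "sample_size_q",
) -> pd.DataFrame:
    """Attach a quartile-coded sample-size covariate to the effect table."""
    per_sample = sample_table.set_index("sample_id")["participant_n"]
    if recompute:
        cutpoints = compute_size_cutpoints(per_sample.to_numpy())
    out = effects.copy()
    n = per_sample.reindex(out["sample_id"]).to_numpy()
    out[column] = sample_size_quartile(n, cutpoints)
    return out


# ---------------------------------------------------------------------------
# multiplicity summary


def summarize_multiplicity(effects: pd.DataFrame) -> pd.DataFrame:
    """Counts of effects/samples/studies by how many studies share a sample."""
    per_sample = effects.groupby("sample_id").agg(
        n_studies=("study_id", "nunique"), n_effects=("effect_id", "count")
    )
    rows = []
    for mult, grp in per_sample.groupby("n_studies"):
        sample_ids = grp.index
        sub = effects[effects["sample_id"].isin(sample_ids)]
        rows.append(
            {
                "studies_per_sample": int(mult),
                "n_samples": len(grp),
                "n_effects": int(grp["n_effects"].sum()),
                "n_studies": int(sub["study_id"].nunique()),
            }
        )
    return pd.DataFrame(rows).sort_values("studies_per_sample").reset_index(drop=True)


# ---------------------------------------------------------------------------
# dummy coding


@dataclass
class CodedMatrix:
    """Reference-coded design matrix aligned with an effect table.

    ``X`` holds k−1 dummy columns per categorical variable, named
    ``"<variable>:<category>"``; ``cluster`` is the sample id per row.
    """

    X: pd.DataFrame
    cluster: np.ndarray
    y: Optional[np.ndarray] = None
    sampling_var: Optional[np.ndarray] = None
    variables: dict = field(default_factory=dict)  # name -> category list
    reference: dict = field(default_factory=dict)  # name -> reference category
    columns_by_variable: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.X)

    def manifest(self) -> dict:
        return {
            name: {
                "reference": self.reference[name],
                "categories": list(self.variables[name]),
                "columns": list(self.columns_by_variable[name]),
            }
            for name in self.variables
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=2)


def code_design_matrix(
    effects: pd.DataFrame,
    variables: dict[str, Sequence[str]],
    reference: Optional[dict[str, str]] = None,
    response: Optional[str] = None,
    sampling_var: Optional[str] = None,
    unknown_label: str = UNKNOWN_LABEL,
) -> CodedMatrix:
    """Build the reference-coded design matrix for the listed variables.

    ``variables`` maps each covariate to its declared category set; the first
    category is the reference unless overridden via ``reference``.  Missing
    values are mapped to ``unknown_label`` (appended to the category set if
    needed); a non-missing value outside the declared set raises.
    """
    reference = dict(reference or {})
    X_cols: dict[str, np.ndarray] = {}
    var_out: dict[str, list[str]] = {}
    cols_by_var: dict[str, list[str]] = {}

    for name, cats in variables.items():
        cats = list(cats)
        if name not in effects.columns:
            raise DatasetValidationError(f"variable '{name}' not in effect table")
        vals = effects[name].astype(object).to_numpy(copy=True)
        missing = pd.isna(vals)
        if missing.any():
            if unknown_label not in cats:
                cats.append(unknown_label)
            vals[missing] = unknown_label
        unseen = sorted(set(vals) - set(cats))
        if unseen:
            raise DatasetValidationError(
                f"variable '{name}': values {unseen} outside declared categories {cats}"
            )
        ref = reference.get(name, cats[0])
        if ref not in cats:
            raise DatasetValidationError(
                f"variable '{name}': reference '{ref}' not among categories"
            )
        reference[name] = ref
        var_out[name] = cats
        cols_by_var[name] = []
        for cat in cats:
            if cat == ref:
                continue
            col = f"{name}:{cat}"
            X_cols[col] = (vals == cat).astype(float)
            cols_by_var[name].append(col)

    X = pd.DataFrame(X_cols, index=effects.index)
    y = effects[response].to_numpy(dtype=float) if response else None
    sv = effects[sampling_var].to_numpy(dtype=float) if sampling_var else None
    if sv is not None and (np.any(np.isnan(sv)) or np.any(sv < 0)):
        raise DatasetValidationError("sampling variances must be present and >= 0")
    return CodedMatrix(
        X=X,
        cluster=effects["sample_id"].to_numpy(),
        y=y,
        sampling_var=sv,
        variables=var_out,
        reference=reference,
        columns_by_variable=cols_by_var,
    )


def decode_design_matrix(coded: CodedMatrix) -> pd.DataFrame:
    """Invert :func:`code_design_matrix` back to category labels."""
    out = {}
    for name, cats in coded.variables.items():
        ref = coded.reference[name]
        vals = np.full(coded.n, ref, dtype=object)
        for col in coded.columns_by_variable[name]:
            cat = col.split(":", 1)[1]
            vals[coded.X[col].to_numpy() == 1.0] = cat
        out[name] = vals
    return pd.DataFrame(out, index=coded.X.index)
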