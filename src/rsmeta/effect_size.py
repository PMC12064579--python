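"""Standardized mean differences (Cohen's d) from reported summary statistics.

Primary studies of response shift report a heterogeneous mix of statistics for
the baseline vs. then-test (or SEM-adjusted) contrast: means with an SD of the
difference, means with per-timepoint SDs, medians with IQRs, confidence
intervals, t statistics, or a ready-made effect size.  This module turns any
of those into an absolute standardized mean difference

    d = |X̄₁ − X̄₂| / SD

with the SD chosen by a fixed hierarchy: SD of the difference in means, then
the pooled SD of the two timepoints, then the baseline SD.  When no SD is
directly available, median/IQR, CI or t statistics are first converted to a
mean and SD; when even that fails, a reported effect size is used as-is.
All results are absolute values: with heterogeneous outcome directions across
studies the sign of a response-shift contrast is not comparable.

Median/IQR conversion follows the Wan et al. (2014) estimators (mean from the
quartile average, SD from the IQR with an n-adjusted normal-theory divisor).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats


class InestimableEffectSizeError(ValueError):
    """No usable combination of inputs to compute or recover an effect size."""


class EffectSizeValidationError(ValueError):
    """Inputs violate an ordering or range invariant."""


class SDSource(str, enum.Enum):
    SD_OF_DIFFERENCE = "sd_of_difference"
    POOLED = "pooled"
    BASELINE = "baseline"
    FROM_REPORTED = "from_reported"


class ConversionPath(str, enum.Enum):
    DIRECT = "direct"
    FROM_MEDIAN_IQR = "from_median_iqr"
    FROM_CI = "from_ci"
    FROM_T = "from_t"
    REPORTED = "reported"


@dataclass(frozen=True)
class EffectSizeSource:
    """Summary statistics a primary study reported for one effect.

    Score-scale quantities (means, SDs, medians, CI bounds) share the PROM's
    units; ``t_stat`` and ``reported_d`` are unitless.  ``median``/``q1``/
    ``q3`` and ``ci_low``/``ci_high`` describe the baseline-minus-then-test
    *difference* distribution.
    """

    mean_baseline: Optional[float] = None
    mean_thentest: Optional[float] = None
    sd_diff: Optional[float] = None
    sd_baseline: Optional[float] = None
    sd_followup: Optional[float] = None
    n: Optional[int] = None
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: float = 0.95
    t_stat: Optional[float] = None
    reported_d: Optional[float] = None

    def __post_init__(self) -> None:
        if self.median is not None and self.q1 is not None and self.q3 is not None:
            if not (self.q1 <= self.median <= self.q3):
                raise EffectSizeValidationError(
                    f"quartile ordering violated: q1={self.q1}, median={self.median}, q3={self.q3}"
                )
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise EffectSizeValidationError(
                    f"ci_low={self.ci_low} exceeds ci_high={self.ci_high}"
                )
        if self.n is not None and self.n < 2:
            raise EffectSizeValidationError(f"n={self.n} must be >= 2")


@dataclass(frozen=True)
class EffectSizeResult:
    d_abs: float
    sd_used: SDSource
    conversion_path: ConversionPath

    def __post_init__(self) -> None:
        if self.d_abs < 0:
            raise EffectSizeValidationError("d_abs must be non-negative")


def iqr_divisor(n: int) -> float:
    """n-adjusted normal-theory divisor eta(n) with SD ≈ IQR / eta(n).

    Wan et al. (2014): eta(n) = 2 * Phi^{-1}((0.75 n − 0.125) / (n + 0.25)),
    which tends to 2 * Phi^{-1}(0.75) ≈ 1.349 as n grows.
    """
    if n < 2:
        raise EffectSizeValidationError(f"n={n} must be >= 2")
    return 2.0 * stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))


def mean_sd_from_median_iqr(
    median: float, q1: float, q3: float, n: int
) -> tuple[float, float]:
    """Estimate (mean, sd) of an approximately normal variable from quartiles.

    mean ≈ (q1 + median + q3) / 3 and sd ≈ (q3 − q1) / eta(n).
    """
    if not (q1 <= median <= q3):
        raise EffectSizeValidationError(
            f"quartile ordering violated: q1={q1}, median={median}, q3={q3}"
        )
    mean = (q1 + median + q3) / 3.0
    sd = (q3 - q1) / iqr_divisor(n)
    return mean, sd


def sd_from_ci(
    mean_diff: float, ci_low: float, ci_high: float, n: int, level: float = 0.95
) -> float:
    """Invert a t-based CI for a within-person mean difference to its SD.

    The CI half-width is t_{(1+level)/2, n−1} * sd / sqrt(n), so
    sd = sqrt(n) * (ci_high − ci_low) / (2 t).  ``mean_diff`` is accepted for
    interface symmetry; the SD depends only on the width.
    """
    if ci_low > ci_high:
        raise EffectSizeValidationError(f"ci_low={ci_low} exceeds ci_high={ci_high}")
    if n < 2:
        raise EffectSizeValidationError(f"n={n} must be >= 2")
    if not 0.0 < level < 1.0:
        raise EffectSizeValidationError(f"confidence level {level} not in (0, 1)")
    t_crit = stats.t.ppf((1.0 + level) / 2.0, df=n - 1)
    return math.sqrt(n) * (ci_high - ci_low) / (2.0 * t_crit)


def sd_from_t(mean_diff: float, t_stat: float, n: int) -> float:
    """Recover the SD of a within-person difference from its paired t statistic.

    t = mean_diff / (sd / sqrt(n))  =>  sd = |mean_diff| sqrt(n) / |t|.
    """
    if t_stat == 0:
        raise InestimableEffectSizeError("t statistic of 0 cannot be inverted to an SD")
    if n is None or n < 2:
        raise EffectSizeValidationError(f"n={n} must be >= 2")
    return abs(mean_diff) * math.sqrt(n) / abs(t_stat)


def pooled_sd(
    sd1: float, sd2: float, n1: Optional[int] = None, n2: Optional[int] = None
) -> float:
    """Pooled SD of two timepoints.

    Equal-weight form sqrt((sd1² + sd2²)/2) when group sizes are equal or
    unknown; df-weighted otherwise.
    """
    if n1 is not None and n2 is not None and n1 != n2:
        return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return math.sqrt((sd1**2 + sd2**2) / 2.0)


def cohens_d(source: EffectSizeSource) -> EffectSizeResult:
    """Absolute Cohen's d from whatever the study reported.

    The SD hierarchy (SD of the difference ≻ pooled ≻ baseline) is applied to
    directly reported SDs first; failing that, median/IQR, CI and t statistics
    are converted to a mean difference and SD of the difference; failing that,
    a reported effect size is taken at absolute value.

    Raises
    ------
    InestimableEffectSizeError
        If no combination of inputs yields an effect size.  Such effects are
        excluded upstream (only effects whose size can be calculated or was
        reported enter the magnitude analysis).
    """
    have_means = source.mean_baseline is not None and source.mean_thentest is not None

    if have_means:
        diff = source.mean_baseline - source.mean_thentest
        # direct hierarchy on reported SDs
        if source.sd_diff is not None:
            return _finish(diff, source.sd_diff, SDSource.SD_OF_DIFFERENCE, ConversionPath.DIRECT)
        if source.sd_baseline is not None and source.sd_followup is not None:
            sd = pooled_sd(source.sd_baseline, source.sd_followup)
            return _finish(diff, sd, SDSource.POOLED, ConversionPath.DIRECT)
        if source.sd_baseline is not None:
            return _finish(diff, source.sd_baseline, SDSource.BASELINE, ConversionPath.DIRECT)
        # converted SDs of the difference
        if source.ci_low is not None and source.ci_high is not None and source.n is not None:
            sd = sd_from_ci(diff, source.ci_low, source.ci_high, source.n, source.ci_level)
            return _finish(diff, sd, SDSource.SD_OF_DIFFERENCE, ConversionPath.FROM_CI)
        if source.t_stat is not None and source.n is not None:
            sd = sd_from_t(diff, source.t_stat, source.n)
            if sd == 0.0:
                # zero mean difference: d is 0 regardless of scale
                return EffectSizeResult(0.0, SDSource.SD_OF_DIFFERENCE, ConversionPath.FROM_T)
            return _finish(diff, sd, SDSource.SD_OF_DIFFERENCE, ConversionPath.FROM_T)

    # no usable means: the quartile summary of the difference provides both
    if (
        source.median is not None
        and source.q1 is not None
        and source.q3 is not None
        and source.n is not None
    ):
        mean_diff, sd = mean_sd_from_median_iqr(source.median, source.q1, source.q3, source.n)
        if sd == 0.0 and mean_diff == 0.0:
            return EffectSizeResult(0.0, SDSource.SD_OF_DIFFERENCE, ConversionPath.FROM_MEDIAN_IQR)
        return _finish(mean_diff, sd, SDSource.SD_OF_DIFFERENCE, ConversionPath.FROM_MEDIAN_IQR)

    if source.reported_d is not None:
        return EffectSizeResult(
            abs(source.reported_d), SDSource.FROM_REPORTED, ConversionPath.REPORTED
        )

    raise InestimableEffectSizeError(
        "no usable inputs: need means plus an SD/CI/t, a median/IQR summary, or a reported d"
    )


def _finish(
    diff: float, sd: float, sd_used: SDSource, path: ConversionPath
) -> EffectSizeResult:
    if sd < 0:
        raise EffectSizeValidationError(f"negative SD {sd}")
    if sd == 0.0:
        if diff == 0.0:
            return EffectSizeResult(0.0, sd_used, path)
        raise InestimableEffectSizeError("zero SD with non-zero mean difference")
    return EffectSizeResult(abs(diff) / sd, sd_used, path)


# ---------------------------------------------------------------------------
# tabular interface

_SOURCE_FIELDS = [
    "mean_baseline", "mean_thentest", "sd_diff", "sd_baseline", "sd_followup",
    "n", "median", "q1", "q3", "ci_low", "ci_high", "ci_level", "t_stat",
    "reported_d",
]


def effect_sizes_from_frame(frame) -> "pandas.DataFrame":  # noqa: F821
    """Apply :func:`cohens_d` row-wise to a DataFrame of reported statistics.

    Unknown columns are preserved; three columns are appended: ``d_abs``,
    ``sd_used`` and ``conversion_path``.  Rows with no estimable effect size
    get NaN / empty markers rather than raising, mirroring upstream exclusion.
    """
    import pandas as pd

    out = frame.copy()
    d_abs, sd_used, path = [], [], []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in _SOURCE_FIELDS:
            if f in frame.columns and pd.notna(row[f]):
                kwargs[f] = int(row[f]) if f == "n" else float(row[f])
        try:
            res = cohens_d(EffectSizeSource(**kwargs))
            d_abs.append(res.d_abs)
            sd_used.append(res.sd_used.value)
            path.append(res.conversion_path.value)
        except (InestimableEffectSizeError, EffectSizeValidationError):
            d_abs.append(np.nan)
            sd_used.append("")
            path.append("inestimable")
    out["d_abs"] = d_abs
    out["sd_used"] = sd_used
    out["conversion_path"] = path
    return out
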