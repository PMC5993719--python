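"""Group-comparison statistics and boxplot summaries.

Cohorts (aspect ratios, angles, phase durations) are compared with the
two-sided Mann-Whitney U test; descriptive summaries follow the Tukey
boxplot convention with type-7 (linear-interpolation) quartiles, the
default of R's ``quantile`` and ``boxplot``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .errors import EmptyInputError

__all__ = ["TestResult", "mann_whitney", "BoxplotStats", "boxplot_stats"]

#: Largest per-group size for which the exact null distribution is used
#: (requires tie-free data); above it, or with ties, the normal
#: approximation with tie and continuity corrections applies.
EXACT_N_MAX = 8


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney U comparison of two samples."""

    U: float
    p_value: float
    n1: int
    n2: int
    method: str  # 'exact' | 'normal-approximation'


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``U`` is the statistic of the first sample.  The exact null
    distribution is used for tie-free samples with both sizes <= 8,
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX
    res = mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method="exact" if exact else "normal-approximation",
    )


@dataclass(frozen=True)
class BoxplotStats:
    """Tukey boxplot summary: quartiles, whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_stats(values) -> BoxplotStats:
    """Tukey convention: whiskers to the most extreme point within
    1.5 x IQR of the quartiles; points beyond are outliers.  Quartiles use
    linear interpolation (type 7)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyInputError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )
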