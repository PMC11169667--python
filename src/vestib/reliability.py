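"""Concurrent-validity and test-retest reliability statistics.

Validity between the digital and clinic-administered forms is assessed
with bivariate Pearson correlations; test-retest reliability with the
single-measure, absolute-agreement intraclass correlation from a two-way
random-effects model, ICC(2,1), with an F-based 95% confidence interval.
Interpretation bands follow the conventional cut-points used in the
clinical literature:

========  =============================  ==========================
value     Pearson r (validity)           ICC (reliability)
========  =============================  ==========================
boundary  r <= 0.25: little or none      icc < 0.50: poor
          0.25 < r < 0.50: low to fair   0.50 <= icc <= 0.75: moderate
          0.50 <= r < 0.75: moderate     0.75 < icc <= 0.90: good
                        to good
          r >= 0.75: strong              icc > 0.90: excellent
========  =============================  ==========================

Boundary ownership: r = 0.75 is "strong", r = 0.50 is "moderate to good",
r = 0.25 is "little or no relationship"; icc = 0.90 is "good" and 0.50 is
"moderate".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "MDC_REGISTRY",
    "pearson_r",
    "icc_2_1",
    "interpret_validity",
    "interpret_reliability",
    "mdc_exceeded",
]

#: Published minimal detectable change per instrument.
MDC_REGISTRY = {"dhi": 18.0, "drs": 1.0, "vas_dizziness": 4.3}


@dataclass(frozen=True)
class ReliabilityResult:
    statistic: str  # 'pearson_r' or 'icc_2_1'
    value: float
    band: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def interpret_validity(r: float) -> str:
    """Interpretation band for a Pearson validity coefficient."""
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r <= 0.25:
        return "little or no relationship"
    if r < 0.50:
        return "low to fair"
    if r < 0.75:
        return "moderate to good"
    return "strong"


def interpret_reliability(icc: float) -> str:
    """Interpretation band for an intraclass correlation coefficient."""
    if icc > 1.0 + 1e-12:
        raise ValueError(f"ICC {icc} exceeds 1")
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> ReliabilityResult:
    """Product-moment correlation with its interpretation band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("pearson_r requires n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    return ReliabilityResult("pearson_r", r, interpret_validity(r))


def icc_2_1(matrix: Sequence[Sequence[float]], alpha: float = 0.05) -> ReliabilityResult:
    """Single-measure absolute-agreement ICC from a two-way random model.

    ``matrix`` is subjects x raters (typically two sessions).  The point
    estimate is ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``
    from the two-way ANOVA mean squares; the confidence interval follows
    the standard F-based construction for ICC(A,1).  Missing values are an
    error — complete cases only, no imputation.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least 2 rater columns")
    n, k = m.shape
    if n < 3:
        raise ValueError("icc_2_1 requires at least 3 subjects")
    if np.isnan(m).any():
        raise ValueError("matrix contains missing values; complete cases only")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    ci_low, ci_high = _icc_a1_ci(icc, msr, msc, mse, n, k, alpha)
    return ReliabilityResult("icc_2_1", float(icc), interpret_reliability(float(icc)),
                             ci_low=ci_low, ci_high=ci_high)


def _icc_a1_ci(icc, msr, msc, mse, n, k, alpha):
    """F-based CI for ICC(A,1) via the Satterthwaite degrees of freedom."""
    if mse == 0:
        return (1.0, 1.0) if icc == 1.0 else (float("nan"), float("nan"))
    fj = msc / mse
    a = k * icc * fj + n * (1.0 + (k - 1.0) * icc) - k * icc
    vn = (k - 1.0) * (n - 1.0) * a**2
    vd = (n - 1.0) * k**2 * icc**2 * fj**2 + (n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2
    v = vn / vd
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(lower), float(upper)


def mdc_exceeded(instrument: str, pre: float, post: float) -> bool:
    """Did the pre-to-post change exceed the instrument's minimal detectable change?"""
    try:
        mdc = MDC_REGISTRY[instrument]
    except KeyError:
        raise ValueError(
            f"no registered MDC for instrument {instrument!r}; known: {sorted(MDC_REGISTRY)}"
        ) from None
    return abs(post - pre) > mdc
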