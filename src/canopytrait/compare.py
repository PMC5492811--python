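"""Cross-sensor intercomparison and treatment-discrimination statistics.

Two questions are answered here.  First, do two sensors deliver the
same vegetation-index values over the same plots and dates?  That is
scored by the R^2 and the discrepancy of slope DS = 1 - slope of the
between-sensor regression (DS = 0 means slope-consistency with the 1:1
line).  Second, can a sensor's index values separate two treatments?
Each treatment's values are summarized by a fitted normal distribution
and their overlap is measured by the Bhattacharyya coefficient

    BC = integral sqrt(t1(x) * t2(x)) dx,

which is 1 for identical distributions and 0 in the limit of complete
separation; 1 - BC is reported as the separation score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "IntercompResult",
    "SeparationResult",
    "intercompare",
    "fit_treatment_normals",
    "bhattacharyya_coefficient",
    "bhattacharyya_normal_closed_form",
    "separation",
]


@dataclass(frozen=True)
class IntercompResult:
    index: str
    slope: float
    intercept: float
    r2: float
    n: int

    @property
    def ds(self) -> float:
        """Discrepancy of slope: 1 - slope of the between-sensor fit."""
        return 1.0 - self.slope


@dataclass(frozen=True)
class SeparationResult:
    index: str
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    b_coeff: float

    def __post_init__(self):
        if not -1e-12 <= self.b_coeff <= 1 + 1e-12:
            raise ValueError("Bhattacharyya coefficient must lie in [0, 1]")

    @property
    def separation(self) -> float:
        """1 - BC: 0 for totally overlapping, 1 for fully separated."""
        return 1.0 - self.b_coeff


def intercompare(vi_a, vi_b, index: str = "") -> IntercompResult:
    """Regress sensor-b index values on paired sensor-a values.

    Pairs must already be aligned on plot x date.  By convention the
    predictor is the UAV value and the response the ground value; the
    direction is the caller's choice and flips DS accordingly.
    """
    a = np.asarray(vi_a, float)
    b = np.asarray(vi_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired index series must be matching 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    sxx = float(np.sum((a - a.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in the predictor series")
    slope = float(np.sum((a - a.mean()) * (b - b.mean())) / sxx)
    intercept = float(b.mean() - slope * a.mean())
    resid = b - (intercept + slope * a)
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return IntercompResult(index=index, slope=slope, intercept=intercept, r2=r2, n=a.size)


def fit_treatment_normals(values_by_treatment: dict) -> dict:
    """Sample mean and sample sd (n-1 denominator) per treatment.

    A treatment with fewer than 2 values, or with zero spread, cannot
    describe a normal distribution and is rejected.
    """
    out = {}
    for name, values in values_by_treatment.items():
        v = np.asarray(values, float)
        if v.size < 2:
            raise ValueError(f"treatment {name!r} needs at least 2 values")
        sd = float(np.std(v, ddof=1))
        if sd == 0:
            raise ValueError(f"treatment {name!r} has zero spread")
        out[name] = (float(v.mean()), sd)
    return out


def bhattacharyya_normal_closed_form(m1, s1, m2, s2) -> float:
    """Closed-form BC of two normal densities (the independent check)."""
    s1, s2 = float(s1), float(s2)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    var_sum = s1**2 + s2**2
    return float(
        np.sqrt(2.0 * s1 * s2 / var_sum) * np.exp(-((m1 - m2) ** 2) / (4.0 * var_sum))
    )


def bhattacharyya_coefficient(m1, s1, m2, s2) -> float:
    """BC of two fitted normals by adaptive numeric integration.

    Integrates sqrt(t1 * t2) over an interval covering both densities;
    agrees with the normal-normal closed form to 1e-8 or better.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    t1 = stats.norm(m1, s1)
    t2 = stats.norm(m2, s2)
    lo = min(m1 - 12 * s1, m2 - 12 * s2)
    hi = max(m1 + 12 * s1, m2 + 12 * s2)

    def integrand(x):
        return np.sqrt(t1.pdf(x) * t2.pdf(x))

    val, _ = integrate.quad(integrand, lo, hi, limit=200, epsabs=1e-12, epsrel=1e-12)
    return float(min(val, 1.0))


def separation(values_t1, values_t2, index: str = "") -> SeparationResult:
    """Treatment separation score 1 - BC from two samples."""
    normals = fit_treatment_normals({"t1": values_t1, "t2": values_t2})
    (m1, s1), (m2, s2) = normals["t1"], normals["t2"]
    bc = bhattacharyya_coefficient(m1, s1, m2, s2)
    return SeparationResult(
        index=index, mean_t1=m1, sd_t1=s1, mean_t2=m2, sd_t2=s2, b_coeff=bc
    )
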