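"""Allometric log-log regression and the rank-correlation suite.

Allometric relationships between biomechanical quantities (bite force vs
muscle volume, modulus/thickness vs cuticle brightness) are fitted by
ordinary least squares on log10-transformed data, the standard approach for
power laws y = a·x^b with multiplicative scatter.  Rank correlations use
Spearman's ρ with average ranks for ties and a t-approximation p-value with
n−2 degrees of freedom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "LogLogFit",
    "CorrelationResult",
    "BoundsVerdict",
    "loglog_ols",
    "spearman",
    "exponent_bounds_test",
    "group_compare",
]


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit of log10(y) on log10(x)."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    n: int
    resid_sd: float

    def predict(self, x):
        """Predicted y (linear scale) at positive x."""
        x = np.asarray(x, dtype=float)
        return 10.0 ** (self.intercept + self.slope * np.log10(x))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    df: int
    p_value: float
    pair: tuple = ("x", "y")
    degenerate: bool = False


class Verdict(str, enum.Enum):
    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"


@dataclass(frozen=True)
class BoundsVerdict:
    verdict: Verdict
    bounds: tuple
    ci_overlaps_interval: bool
    ci_excludes_lower: bool
    ci_excludes_upper: bool


def _validated_log10(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    bad = ~(x > 0) | ~np.isfinite(x)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{name} must be strictly positive and finite for a log-log fit; "
            f"offending record index {idx} (value {x[idx]!r})"
        )
    return np.log10(x)


def loglog_ols(x, y, alpha: float = 0.05) -> LogLogFit:
    """OLS regression of log10(y) on log10(x) with a t-based slope CI.

    Parameters
    ----------
    x, y : array-like of strictly positive values, n ≥ 3.
    alpha : CI level is 1 − alpha (default 95%).
    """
    lx = _validated_log10(x, "x")
    ly = _validated_log10(y, "y")
    if lx.size != ly.size:
        raise ValueError("x and y must have equal length")
    n = lx.size
    if n < 3:
        raise ValueError("need at least 3 points for a log-log fit")
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = model.conf_int(alpha=alpha)
    resid_sd = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    return LogLogFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        r2=float(model.rsquared),
        n=n,
        resid_sd=resid_sd,
    )


def spearman(x, y, pair=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with d.f. = n − 2 and a t-approximation p.

    Ties receive average ranks.  Constant input yields an undefined ρ,
    returned as NaN with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, n - 2, np.nan, tuple(pair), degenerate=True)
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), n - 2, float(res.pvalue), tuple(pair))


def exponent_bounds_test(fit: LogLogFit, bounds=(2.0 / 3.0, 1.0)) -> BoundsVerdict:
    """Compare a fitted scaling exponent to a closed theoretical interval.

    The default interval is the muscle-scaling prediction: a lower bound from
    geometric similarity (force ∝ volume^(2/3)) and an upper bound from
    constant fibre length (force ∝ volume).  The verdict is based on the
    point estimate; CI overlap with the interval is reported alongside.
    """
    lo, hi = bounds
    if lo > hi:
        raise ValueError("bounds must be ordered")
    if fit.slope < lo:
        verdict = Verdict.BELOW
    elif fit.slope > hi:
        verdict = Verdict.ABOVE
    else:
        verdict = Verdict.WITHIN
    return BoundsVerdict(
        verdict=verdict,
        bounds=(lo, hi),
        ci_overlaps_interval=not (fit.ci_high < lo or fit.ci_low > hi),
        ci_excludes_lower=(fit.ci_low > lo) or (fit.ci_high < lo),
        ci_excludes_upper=(fit.ci_low > hi) or (fit.ci_high < hi),
    )


def group_compare(a, b, test: str = "t"):
    """Two-sample comparison: Student's t ("t") or Wilcoxon rank sum
    ("wilcoxon", reported as the Mann–Whitney W of the first sample).

    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if test == "t":
        res = sps.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
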