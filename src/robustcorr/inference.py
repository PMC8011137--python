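"""Confidence intervals and hypothesis tests for robust correlations.

The interval uses the Fisher transformation ``F = arctanh(r)`` with the
modified variance estimate ``(1 + 0.5 r^2) / (n - 3)`` appropriate for
robust correlation measures (Bonett–Wright style), and the test statistic
is ``t = r * sqrt((n - 2) / (1 - 0.5 r^2))`` on ``n - 2`` degrees of
freedom.  Unlike the classical Pearson t statistic, this one stays finite
at ``|r| = 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm, t as t_dist

from .estimators import CorrelationEstimate

__all__ = ["IntervalEstimate", "TestResult", "fisher_ci", "corr_test"]

_SIDES = {"two": "two", "two_sided": "two", "two-sided": "two",
          "lower": "lower", "upper": "upper"}
_ALTERNATIVES = {"two_sided": "two_sided", "two-sided": "two_sided",
                 "two": "two_sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class IntervalEstimate:
    """A confidence interval for a correlation coefficient."""

    lcl: float
    ucl: float
    level: float
    sided: str

    def __iter__(self):
        return iter((self.lcl, self.ucl))


@dataclass(frozen=True)
class TestResult:
    """Result of the t test of H0: rho = 0."""

    t: float
    df: int
    p: float
    alternative: str


def _unpack(r, n):
    if isinstance(r, CorrelationEstimate):
        if n is None:
            n = r.n
        r = r.r
    if n is None:
        raise ValueError("n is required when r is a plain number")
    r = float(r)
    n = int(n)
    if n < 4:
        raise ValueError("inference requires n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    return r, n


def fisher_ci(r, n: int | None = None, level: float = 0.95,
              sided: str = "two") -> IntervalEstimate:
    """Fisher-transform confidence interval with modified variance.

    ``LCL = tanh(arctanh(r) - z * sqrt((1 + 0.5 r^2)/(n - 3)))`` and the
    mirror image for the UCL, with ``z`` the normal quantile at
    ``1 - alpha/2`` (two-sided) or ``1 - alpha`` (one-sided; the unused
    limit is set to -1 or +1).

    ``r`` may be a :class:`CorrelationEstimate`, in which case ``n`` is
    taken from it.  At ``|r| = 1`` the transform diverges and the
    degenerate interval ``[r, r]`` is returned with a warning.
    """
    r, n = _unpack(r, n)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    try:
        sided = _SIDES[sided.lower()]
    except KeyError:
        raise ValueError(f"sided must be one of {sorted(set(_SIDES))}") from None
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: Fisher transform diverges; returning the "
                      "degenerate interval [r, r]", stacklevel=2)
        return IntervalEstimate(r, r, level, sided)
    alpha = 1.0 - level
    se = math.sqrt((1.0 + 0.5 * r * r) / (n - 3))
    f = math.atanh(r)
    if sided == "two":
        z = norm.ppf(1.0 - alpha / 2.0)
        return IntervalEstimate(math.tanh(f - z * se), math.tanh(f + z * se),
                                level, sided)
    z = norm.ppf(1.0 - alpha)
    if sided == "lower":
        return IntervalEstimate(math.tanh(f - z * se), 1.0, level, sided)
    return IntervalEstimate(-1.0, math.tanh(f + z * se), level, sided)


def corr_test(r, n: int | None = None,
              alternative: str = "two_sided") -> TestResult:
    """Test H0: rho = 0 using ``t = r * sqrt((n - 2)/(1 - 0.5 r^2))``.

    The p-value comes from the t distribution with ``n - 2`` degrees of
    freedom under the chosen alternative (``two_sided``, ``greater`` or
    ``less``).  The statistic is finite even at ``|r| = 1``.
    """
    r, n = _unpack(r, n)
    try:
        alternative = _ALTERNATIVES[alternative.lower()]
    except KeyError:
        raise ValueError(
            f"alternative must be one of {sorted(set(_ALTERNATIVES))}"
        ) from None
    df = n - 2
    t = r * math.sqrt(df / (1.0 - 0.5 * r * r))
    if alternative == "two_sided":
        p = 2.0 * t_dist.sf(abs(t), df)
    elif alternative == "greater":
        p = t_dist.sf(t, df)
    else:
        p = t_dist.cdf(t, df)
    return TestResult(t, df, float(min(p, 1.0)), alternative)
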