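"""Bounded influence transform, robust scale estimators, and rank utilities.

This module holds the primitives that every robust correlation estimator in
the package is built from:

* :func:`t_omega` — the redescending transform ``T_w(x) = x * sech(w * x)``.
  For ``w > 0`` it is odd, bounded, has unit derivative at the origin, and
  returns toward zero as ``|x|`` grows, so gross outliers are progressively
  discounted rather than merely capped.  ``w = 0`` gives the identity, which
  recovers the classical (non-robust) limiting estimators.
* :func:`sn_scale` and :func:`qn_scale` — the Rousseeuw–Croux Sn and Qn
  high-breakdown scale estimators, with the usual consistency constants and
  finite-sample correction factors so that both are consistent for the
  standard deviation under normality.
* :func:`robust_standardize` — median/Sn (or Qn) z-scores of a paired sample.
* :func:`midranks` — ordinal standings with mid-ranks for ties.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "t_omega",
    "sn_scale",
    "qn_scale",
    "robust_scale",
    "robust_standardize",
    "StandardizedPair",
    "midranks",
]

# Asymptotic consistency constant for Sn (makes Sn estimate sigma under
# normality) and the Croux-Rousseeuw finite-sample correction factors.
_SN_CONSTANT = 1.1926
_SN_SMALL_N = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351, 6: 0.993, 7: 1.198,
               8: 1.005, 9: 1.131}

# Qn constant 1 / (sqrt(2) * Phi^{-1}(5/8)) and its small-sample factors.
_QN_CONSTANT = 2.21914
_QN_SMALL_N = {2: 0.399, 3: 0.994, 4: 0.512, 5: 0.844, 6: 0.611, 7: 0.857,
               8: 0.669, 9: 0.872}


def _as_vector(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must contain only finite values")
    return arr


def t_omega(x, omega: float):
    """Redescending influence transform ``x / cosh(omega * x)``.

    Parameters
    ----------
    x : float or array-like
        Finite input value(s).
    omega : float
        Nonnegative tuning constant.  ``omega = 0`` yields the identity;
        larger values discount large ``|x|`` more aggressively.

    Returns
    -------
    float or ndarray
        ``x * sech(omega * x)``, elementwise.
    """
    if not (np.isscalar(omega) and math.isfinite(omega)) or omega < 0:
        raise ValueError("omega must be a finite nonnegative scalar")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    # cosh overflows past ~710; the overflowed inf correctly maps to 0.
    with np.errstate(over="ignore"):
        out = arr / np.cosh(omega * arr)
    return out if out.ndim else float(out)


def _sn_correction(n: int) -> float:
    if n <= 9:
        return _SN_SMALL_N[n]
    if n % 2 == 1:
        return n / (n - 0.9)
    return 1.0


def sn_scale(x) -> float:
    """Rousseeuw–Croux Sn scale estimate.

    Sn = c_n * 1.1926 * lowmed_i ( highmed_j |x_i - x_j| ), where for each
    point the *high* median (order statistic ``floor(n/2) + 1``) of its
    absolute differences to all points is taken, followed by the *low*
    median (order statistic ``floor((n+1)/2)``) over points.  The constant
    makes Sn consistent for sigma under normality; ``c_n`` is the
    finite-sample correction.

    Returns zero iff more than half of the observations are tied at a
    single value.  Computed by the plain O(n^2) algorithm, chunked to keep
    memory bounded for large n.
    """
    arr = _as_vector(x)
    n = arr.size
    if n < 2:
        raise InsufficientDataError("sn_scale requires at least 2 observations")
    k_hi = n // 2            # 0-based index of order statistic floor(n/2)+1
    k_lo = (n + 1) // 2 - 1  # 0-based index of order statistic floor((n+1)/2)
    inner = np.empty(n)
    chunk = max(1, int(4_000_000 // n))
    for start in range(0, n, chunk):
        d = np.abs(arr[start:start + chunk, None] - arr[None, :])
        inner[start:start + chunk] = np.partition(d, k_hi, axis=1)[:, k_hi]
    raw = np.partition(inner, k_lo)[k_lo]
    return float(_SN_CONSTANT * _sn_correction(n) * raw)


def _qn_correction(n: int) -> float:
    if n <= 9:
        return _QN_SMALL_N[n]
    if n % 2 == 1:
        return n / (n + 1.4)
    return n / (n + 3.8)


def qn_scale(x) -> float:
    """Rousseeuw–Croux Qn scale estimate.

    The k-th order statistic of the C(n, 2) pairwise absolute differences,
    with ``k = C(h, 2)`` and ``h = floor(n/2) + 1`` (roughly the first
    quartile of the pairwise distances), scaled by 2.21914 and a
    finite-sample correction.  Offered as a plug-in alternative to Sn.
    """
    arr = _as_vector(x)
    n = arr.size
    if n < 2:
        raise InsufficientDataError("qn_scale requires at least 2 observations")
    h = n // 2 + 1
    k = h * (h - 1) // 2
    d = pdist(arr[:, None], metric="cityblock")
    raw = np.partition(d, k - 1)[k - 1]
    return float(_QN_CONSTANT * _qn_correction(n) * raw)


_SCALE_ESTIMATORS = {"sn": sn_scale, "qn": qn_scale}


def robust_scale(x, scale: str = "sn") -> float:
    """Dispatch to the named robust scale estimator (``"sn"`` or ``"qn"``)."""
    try:
        fn = _SCALE_ESTIMATORS[scale.lower()]
    except KeyError:
        raise ValueError(
            f"unknown scale estimator {scale!r}; choose from "
            f"{sorted(_SCALE_ESTIMATORS)}"
        ) from None
    return fn(x)


class StandardizedPair(NamedTuple):
    """Robust z-scores of a paired sample: medians 0, unit robust scale."""

    c1: np.ndarray
    c2: np.ndarray


def robust_standardize(x, y, scale: str = "sn") -> StandardizedPair:
    """Median-center and robust-scale both variables of a paired sample.

    ``c1 = (x - median(x)) / s(x)`` and likewise for ``c2``, where ``s`` is
    the Sn (default) or Qn scale.  Raises :class:`DegenerateDataError` if a
    scale estimate is zero, naming the offending variable.
    """
    xa = _as_vector(x, "x")
    ya = _as_vector(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    sx = robust_scale(xa, scale)
    if sx <= 0.0:
        raise DegenerateDataError(
            f"robust scale of x is zero ({scale}); correlation undefined"
        )
    sy = robust_scale(ya, scale)
    if sy <= 0.0:
        raise DegenerateDataError(
            f"robust scale of y is zero ({scale}); correlation undefined"
        )
    c1 = (xa - np.median(xa)) / sx
    c2 = (ya - np.median(ya)) / sy
    return StandardizedPair(c1, c2)


def midranks(x) -> np.ndarray:
    """Ordinal standings 1..n with ties assigned the mean of spanned ranks."""
    arr = _as_vector(x)
    if arr.size == 0:
        raise InsufficientDataError("midranks requires at least 1 observation")
    return rankdata(arr, method="average")
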