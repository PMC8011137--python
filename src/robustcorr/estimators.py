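"""Robust and classical bivariate correlation estimators.

Three robust estimators form the core of the package:

* :func:`taba` — cosine similarity of the influence-transformed robust
  z-scores.  A bounded-influence analogue of the Pearson correlation for
  linear association.
* :func:`tabwil` — built from the medians of |U| and |V| where U and V are
  the sum and difference of the robust z-scores; a smoothed, bounded
  variant of the Falk median correlation.
* :func:`tabwil_rank` — TabWil applied to mid-ranks; measures monotonic
  association and is invariant under strictly increasing transforms.

Five comparators used in the benchmark are also provided: Pearson,
Spearman, quadrant (sign), median, and MCD (minimum covariance
determinant) correlations.  Every estimator returns a
:class:`CorrelationEstimate` that coerces to ``float``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError
from .influence import midranks, robust_standardize, t_omega

__all__ = [
    "PairedSample",
    "CorrelationEstimate",
    "DEFAULT_OMEGA",
    "METHODS",
    "correlation",
    "taba",
    "tabwil",
    "tabwil_rank",
    "pearson",
    "spearman",
    "quadrant",
    "median_corr",
    "mcd_corr",
]

#: Default tuning constants for the robust estimators.
DEFAULT_OMEGA = {"taba": 0.45, "tabwil": 0.05, "tabwil_rank": 0.05}

MIN_N = 4  # smallest usable paired sample: df = n - 2 >= 2 for inference


class PairedSample(NamedTuple):
    """Two equal-length numeric vectors, the unit of correlation estimation."""

    x: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class CorrelationEstimate:
    """A correlation estimate with its method tag and sample size."""

    method: str
    r: float
    n: int
    omega: float | None = None

    def __float__(self) -> float:
        return self.r

    def __repr__(self) -> str:  # compact, R-style
        om = "" if self.omega is None else f", omega={self.omega:g}"
        return f"CorrelationEstimate({self.method}, r={self.r:.6f}, n={self.n}{om})"


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < MIN_N:
        raise InsufficientDataError(
            f"need at least {MIN_N} paired observations, got {xa.size}"
        )
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("x and y must contain only finite values "
                         "(remove missing values upstream)")
    return xa, ya


def _clip(r: float) -> float:
    return float(min(1.0, max(-1.0, r)))


def taba(x, y, omega: float = 0.45, scale: str = "sn",
         standardize: str = "robust") -> CorrelationEstimate:
    """Taba robust correlation.

    Standardize each variable by its median and Sn (or Qn) scale, pass the
    z-scores through the redescending transform ``T_w``, and take the
    cosine similarity:

        r = sum(T_w(c1) * T_w(c2)) / sqrt(sum(T_w(c1)^2) * sum(T_w(c2)^2))

    ``|r| <= 1`` by Cauchy–Schwarz.  ``standardize="classical"`` swaps in
    mean/SD z-scores, under which ``omega = 0`` reproduces the Pearson
    correlation exactly (the non-robust limit).
    """
    xa, ya = _validate_pair(x, y)
    if standardize == "robust":
        c1, c2 = robust_standardize(xa, ya, scale)
    elif standardize == "classical":
        sx, sy = xa.std(ddof=1), ya.std(ddof=1)
        if sx == 0.0 or sy == 0.0:
            raise DegenerateDataError("zero standard deviation")
        c1 = (xa - xa.mean()) / sx
        c2 = (ya - ya.mean()) / sy
    else:
        raise ValueError("standardize must be 'robust' or 'classical'")
    t1 = t_omega(c1, omega)
    t2 = t_omega(c2, omega)
    denom = math.sqrt(float(np.sum(t1 * t1)) * float(np.sum(t2 * t2)))
    if denom == 0.0:
        raise DegenerateDataError("all transformed residuals are zero")
    r = float(np.sum(t1 * t2)) / denom
    return CorrelationEstimate("taba", _clip(r), xa.size, omega)


def _tabwil_m(c1: np.ndarray, c2: np.ndarray) -> tuple[float, float]:
    """Medians of |U| and |V| for U = c1 + c2, V = c1 - c2."""
    m1 = float(np.median(np.abs(c1 + c2)))
    m2 = float(np.median(np.abs(c1 - c2)))
    return m1, m2


def _tabwil_from_scores(c1, c2, omega, method) -> tuple[float, float, float]:
    m1, m2 = _tabwil_m(c1, c2)
    t1 = t_omega(m1 * m1, omega)
    t2 = t_omega(m2 * m2, omega)
    den = t1 + t2
    if den <= 0.0:
        raise DegenerateDataError(
            f"{method}: medians of |U| and |V| are both zero"
        )
    return (t1 - t2) / den, m1, m2


def tabwil(x, y, omega: float = 0.05, scale: str = "sn") -> CorrelationEstimate:
    """TabWil robust correlation.

    With robust z-scores c1, c2, let U = c1 + c2 and V = c1 - c2,
    m1 = median|U|, m2 = median|V|.  Then

        r = (T_w(m1^2) - T_w(m2^2)) / (T_w(m1^2) + T_w(m2^2)).

    Both transformed terms are nonnegative, so ``r`` lies in [-1, 1]; it is
    0 when m1 = m2, and as ``omega -> 0`` it converges to the median
    correlation ``(m1^2 - m2^2) / (m1^2 + m2^2)``.
    """
    xa, ya = _validate_pair(x, y)
    c1, c2 = robust_standardize(xa, ya, scale)
    r, _, _ = _tabwil_from_scores(c1, c2, omega, "tabwil")
    return CorrelationEstimate("tabwil", _clip(r), xa.size, omega)


def tabwil_rank(x, y, omega: float = 0.05, scale: str = "sn") -> CorrelationEstimate:
    """TabWil rank correlation: TabWil applied to mid-ranks.

    Measures the monotonic association and its direction; invariant under
    strictly increasing transforms of either variable.  Suitable for
    ordinal, interval, or ratio data.
    """
    xa, ya = _validate_pair(x, y)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateDataError("a variable with all values tied has no ranks"
                                  " to correlate")
    rx = midranks(xa)
    ry = midranks(ya)
    c1, c2 = robust_standardize(rx, ry, scale)
    r, _, _ = _tabwil_from_scores(c1, c2, omega, "tabwil_rank")
    return CorrelationEstimate("tabwil_rank", _clip(r), xa.size, omega)


def pearson(x, y) -> CorrelationEstimate:
    """Classical product-moment correlation."""
    xa, ya = _validate_pair(x, y)
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    den = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    if den == 0.0:
        raise DegenerateDataError("zero variance in x or y")
    return CorrelationEstimate("pearson", _clip(float(np.dot(xc, yc)) / den),
                               xa.size)


def spearman(x, y) -> CorrelationEstimate:
    """Spearman rank correlation: Pearson on mid-ranks."""
    xa, ya = _validate_pair(x, y)
    est = pearson(midranks(xa), midranks(ya))
    return CorrelationEstimate("spearman", est.r, xa.size)


def quadrant(x, y) -> CorrelationEstimate:
    """Quadrant (sign) correlation with the sin(pi/2 *) consistency transform.

    r = sin(pi/2 * mean_i sign[(x_i - med x)(y_i - med y)]).  Points falling
    exactly on a median contribute zero sign.
    """
    xa, ya = _validate_pair(x, y)
    s = np.sign((xa - np.median(xa)) * (ya - np.median(ya)))
    r = math.sin(0.5 * math.pi * float(s.mean()))
    return CorrelationEstimate("quadrant", _clip(r), xa.size)


def median_corr(x, y, scale: str = "sn") -> CorrelationEstimate:
    """Falk-type median correlation ``(m1^2 - m2^2) / (m1^2 + m2^2)``.

    m1, m2 are the medians of |U| and |V| computed exactly as in
    :func:`tabwil`; this is the ``omega -> 0`` limit of TabWil.
    """
    xa, ya = _validate_pair(x, y)
    c1, c2 = robust_standardize(xa, ya, scale)
    m1, m2 = _tabwil_m(c1, c2)
    den = m1 * m1 + m2 * m2
    if den <= 0.0:
        raise DegenerateDataError("median: medians of |U| and |V| are both zero")
    return CorrelationEstimate("median", _clip((m1 * m1 - m2 * m2) / den),
                               xa.size)


# ---------------------------------------------------------------------------
# Minimum covariance determinant (bivariate comparator)
# ---------------------------------------------------------------------------

def _subset_cov(X: np.ndarray, supp: np.ndarray):
    """Means, covariances and determinants for a batch of support sets.

    supp has shape (S, k); returns mu (S, 2), cov (S, 2, 2), det (S,).
    """
    k = supp.shape[1]
    pts = X[supp]                       # (S, k, 2)
    mu = pts.mean(axis=1)               # (S, 2)
    xc = pts - mu[:, None, :]
    cov = np.einsum("skp,skq->spq", xc, xc) / (k - 1)
    det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
    return mu, cov, det


def mcd_corr(x, y, h: int | None = None, n_starts: int = 500,
             max_csteps: int = 100, seed: int = 0) -> CorrelationEstimate:
    """Correlation from the bivariate minimum covariance determinant.

    FastMCD-style search: ``n_starts`` random elemental (3-point) starts,
    each refined by concentration steps (recompute mean/covariance on the
    ``h`` points with smallest Mahalanobis distance) until the determinant
    stops decreasing; the correlation is read off the raw covariance of the
    best h-subset.  No reweighting step is applied.  Deterministic given
    ``seed``.

    The default subset size is ``h = floor((n + p + 1) / 2)`` with p = 2.
    ``h = n`` gives the classical covariance, hence the Pearson correlation.
    """
    xa, ya = _validate_pair(x, y)
    n = xa.size
    p = 2
    if h is None:
        h = (n + p + 1) // 2
    if not p + 1 <= h <= n:
        raise InsufficientDataError(f"h must lie in [{p + 1}, {n}], got {h}")
    X = np.column_stack([xa, ya])

    def _corr_from_cov(cov: np.ndarray) -> float:
        vxx, vyy, vxy = cov[0, 0], cov[1, 1], cov[0, 1]
        if vxx <= 0.0 or vyy <= 0.0:
            raise DegenerateDataError("a coordinate is constant on the MCD "
                                      "support; correlation undefined")
        return _clip(vxy / math.sqrt(vxx * vyy))

    if h == n:
        cov = np.cov(X, rowvar=False)
        return CorrelationEstimate("mcd", _corr_from_cov(cov), n)

    rng = np.random.default_rng(seed)
    S = n_starts
    # 3 distinct random indices per start
    order = np.argsort(rng.random((S, n)), axis=1)
    supp = order[:, :p + 1]
    det = np.full(S, np.inf)
    cov = None
    for _ in range(max_csteps):
        mu, cov, cur_det = _subset_cov(X, supp)
        # Regularize singular batches so distances stay usable; an exactly
        # singular h-subset is already a global minimum (det = 0).
        safe = np.maximum(cur_det, 1e-30)
        inv = np.empty_like(cov)
        inv[:, 0, 0] = cov[:, 1, 1] / safe
        inv[:, 1, 1] = cov[:, 0, 0] / safe
        inv[:, 0, 1] = inv[:, 1, 0] = -cov[:, 0, 1] / safe
        xc = X[None, :, :] - mu[:, None, :]                # (S, n, 2)
        d2 = np.einsum("snp,spq,snq->sn", xc, inv, xc)
        new_supp = np.argpartition(d2, h - 1, axis=1)[:, :h]
        if supp.shape[1] == h:
            improved = cur_det < det * (1 - 1e-12)
            det = cur_det
            if not improved.any():
                break
        supp = new_supp
    else:  # pragma: no cover - max_csteps is generous
        _, cov, det = _subset_cov(X, supp)
    best = int(np.argmin(det))
    return CorrelationEstimate("mcd", _corr_from_cov(cov[best]), n)


_METHOD_FUNCS = {
    "taba": taba,
    "tabwil": tabwil,
    "tabwil_rank": tabwil_rank,
    "pearson": pearson,
    "spearman": spearman,
    "quadrant": quadrant,
    "median": median_corr,
    "mcd": mcd_corr,
}

#: All estimator tags, robust methods first.
METHODS = tuple(_METHOD_FUNCS)

_ALIASES = {"tabwilrank": "tabwil_rank", "tabwil-rank": "tabwil_rank",
            "median_corr": "median", "mcd_corr": "mcd"}


def correlation(x, y, method: str = "taba", omega: float | None = None,
                **kwargs) -> CorrelationEstimate:
    """Estimate the correlation of (x, y) with the named method.

    ``omega`` defaults to the method's tuning constant (0.45 for Taba,
    0.05 for TabWil and TabWil rank) and is ignored by the comparators.
    Extra keyword arguments are passed through (e.g. ``scale="qn"`` for
    the robust estimators, ``seed=`` for MCD).
    """
    tag = _ALIASES.get(method.lower(), method.lower())
    try:
        fn = _METHOD_FUNCS[tag]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {list(_METHOD_FUNCS)}"
        ) from None
    if tag in DEFAULT_OMEGA:
        if omega is None:
            omega = DEFAULT_OMEGA[tag]
        return fn(x, y, omega=omega, **kwargs)
    if omega is not None:
        raise ValueError(f"method {tag!r} does not take a tuning constant")
    return fn(x, y, **kwargs)
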