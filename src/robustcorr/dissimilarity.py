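"""Pairwise correlation, distance, and p-value matrices over expression data.

Rows of the input table are variables (e.g. genes), columns are samples or
replicates.  All pairwise outputs are exactly symmetric: the upper triangle
is computed once and mirrored.  The default distance convention is
``d = (1 - r) / 2``, pinned by the identity relating Euclidean and Pearson
distances for standardized n-vectors, ``d_Euclid = 2 * sqrt(n * d_Pearson)``.

Also provided: residual-based partial, semi-partial, and generalized partial
correlations, where each outcome may be residualized against its own set of
controls through a linear, logistic, or Poisson model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError
from .estimators import CorrelationEstimate, correlation
from .inference import corr_test

__all__ = [
    "PairwiseMatrix",
    "average_duplicates",
    "corr_matrix",
    "dist_matrix",
    "pvalue_matrix",
    "partial_corr",
    "generalized_partial_corr",
    "read_table",
    "write_matrix",
    "linkage_from_dist",
]

DISTANCE_CONVENTIONS = ("half_one_minus_r", "one_minus_r", "one_minus_abs_r")


@dataclass
class PairwiseMatrix:
    """A square symmetric matrix of pairwise statistics.

    ``kind`` is one of ``correlation`` (diagonal 1, values in [-1, 1]),
    ``distance`` (diagonal 0, values >= 0), or ``pvalue`` (diagonal 0 by
    convention, values in [0, 1]).
    """

    values: pd.DataFrame
    kind: str
    method: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ids(self):
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr, index=[f"v{i}" for i in range(arr.shape[0])])


def average_duplicates(matrix) -> pd.DataFrame:
    """Collapse rows sharing an id to their arithmetic mean.

    Mirrors the usual preprocessing of expression tables where a gene
    appearing several times is represented by its average profile.  Row
    order follows first appearance.
    """
    df = _as_frame(matrix)
    return df.groupby(level=0, sort=False).mean()


def _check_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(
            f"duplicate row ids {dups}; call average_duplicates first"
        )
    if df.isna().any().any():
        bad = [(str(i), str(c)) for i, c in
               zip(*np.nonzero(df.isna().to_numpy()))]
        raise ValueError(f"missing values at (row, column) positions {bad[:10]};"
                         " drop or impute upstream")
    return df


def corr_matrix(matrix, method: str = "taba", omega: float | None = None,
                **kwargs) -> PairwiseMatrix:
    """Pairwise correlation matrix: entry (i, j) is the chosen estimator on
    rows i and j.  Diagonal is 1; the result is exactly symmetric."""
    df = _check_matrix(_as_frame(matrix))
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    data = df.to_numpy(dtype=float)
    k = data.shape[0]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                est = correlation(data[i], data[j], method, omega, **kwargs)
            except DegenerateDataError as exc:
                raise DegenerateDataError(
                    f"rows {df.index[i]!r} / {df.index[j]!r}: {exc}"
                ) from exc
            out[i, j] = out[j, i] = est.r
    frame = pd.DataFrame(out, index=df.index, columns=df.index)
    return PairwiseMatrix(frame, "correlation", method,
                          {"omega": omega, "n_samples": df.shape[1]})


def dist_matrix(corr: PairwiseMatrix,
                convention: str = "half_one_minus_r") -> PairwiseMatrix:
    """Distance matrix from a correlation matrix.

    Conventions: ``half_one_minus_r`` (default) maps r to (1 - r)/2, so a
    perfect positive correlation has distance 0 and a perfect negative one
    distance 1; ``one_minus_r`` maps to 1 - r; ``one_minus_abs_r`` to
    1 - |r| (sign-blind).
    """
    if corr.kind != "correlation":
        raise ValueError(f"expected a correlation matrix, got {corr.kind!r}")
    if convention not in DISTANCE_CONVENTIONS:
        raise ValueError(f"convention must be one of {DISTANCE_CONVENTIONS}")
    r = corr.values.to_numpy()
    if convention == "half_one_minus_r":
        d = (1.0 - r) / 2.0
    elif convention == "one_minus_r":
        d = 1.0 - r
    else:
        d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    frame = pd.DataFrame(d, index=corr.values.index, columns=corr.values.columns)
    meta = dict(corr.meta, convention=convention)
    return PairwiseMatrix(frame, "distance", corr.method, meta)


def pvalue_matrix(matrix, method: str = "taba", omega: float | None = None,
                  alternative: str = "two_sided", adjust: str | None = None,
                  **kwargs) -> PairwiseMatrix:
    """Matrix of p-values for H0: rho = 0 on each row pair.

    The diagonal is 0 by convention and excluded from any adjustment.
    ``adjust="bh"`` applies a Benjamini–Hochberg correction across the
    upper-triangle p-values (off by default).
    """
    corr = corr_matrix(matrix, method, omega, **kwargs)
    n = corr.meta["n_samples"]
    r = corr.values.to_numpy()
    k = r.shape[0]
    p = np.zeros_like(r)
    iu = np.triu_indices(k, 1)
    pvals = np.array([corr_test(rv, n, alternative).p for rv in r[iu]])
    if adjust is not None:
        if adjust.lower() not in {"bh", "fdr_bh"}:
            raise ValueError("adjust must be None or 'bh'")
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
    p[iu] = pvals
    p[(iu[1], iu[0])] = pvals
    frame = pd.DataFrame(p, index=corr.values.index, columns=corr.values.columns)
    meta = dict(corr.meta, alternative=alternative, adjust=adjust)
    return PairwiseMatrix(frame, "pvalue", method, meta)


# ---------------------------------------------------------------------------
# Partial and generalized partial correlations
# ---------------------------------------------------------------------------

def _controls_matrix(controls, n: int) -> np.ndarray | None:
    if controls is None:
        return None
    c = np.asarray(controls, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.size == 0 or c.shape[1] == 0:
        return None
    if c.shape[0] != n:
        raise ValueError("controls must have one row per observation")
    return c


def _ols_residuals(v: np.ndarray, controls: np.ndarray | None) -> np.ndarray:
    if controls is None:
        return v
    design = np.column_stack([np.ones(len(v)), controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("controls are rank deficient (collinear)")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    res = v - design @ beta
    if np.max(np.abs(res)) <= 1e-10 * max(1.0, np.max(np.abs(v))):
        raise DegenerateDataError(
            "outcome lies in the span of its controls; residuals are zero"
        )
    return res


def partial_corr(x, y, controls, method: str = "taba",
                 omega: float | None = None, semi: str | None = None,
                 **kwargs) -> CorrelationEstimate:
    """Robust partial (or semi-partial) correlation.

    Both outcomes are residualized on the controls by ordinary least
    squares (with intercept) and the residuals are correlated with the
    chosen estimator.  ``semi="x"`` or ``semi="y"`` residualizes only that
    side (semi-partial correlation).
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    c = _controls_matrix(controls, xa.size)
    if semi not in (None, "x", "y"):
        raise ValueError("semi must be None, 'x', or 'y'")
    rx = _ols_residuals(xa, c) if semi in (None, "x") else xa
    ry = _ols_residuals(ya, c) if semi in (None, "y") else ya
    return correlation(rx, ry, method, omega, **kwargs)


_FAMILIES = {"linear": sm.families.Gaussian,
             "logistic": sm.families.Binomial,
             "poisson": sm.families.Poisson}


def _glm_residuals(v: np.ndarray, controls: np.ndarray | None, link: str,
                   residual_type: str) -> np.ndarray:
    try:
        family = _FAMILIES[link]()
    except KeyError:
        raise ValueError(f"link must be one of {sorted(_FAMILIES)}") from None
    if link == "logistic" and not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("logistic link requires a binary 0/1 outcome")
    if link == "poisson" and (np.any(v < 0) or np.any(v != np.round(v))):
        raise ValueError("poisson link requires nonnegative integer outcomes")
    if controls is None:
        return v
    design = np.column_stack([np.ones(len(v)), controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("controls are rank deficient (collinear)")
    fit = sm.GLM(v, design, family=family).fit()
    if not fit.converged:
        raise RuntimeError(f"{link} fit did not converge")
    if residual_type == "response":
        res = np.asarray(v - fit.fittedvalues)
    elif residual_type == "pearson":
        res = np.asarray(fit.resid_pearson)
    elif residual_type == "deviance":
        res = np.asarray(fit.resid_deviance)
    else:
        raise ValueError("residual_type must be response, pearson or deviance")
    if np.max(np.abs(res)) <= 1e-10 * max(1.0, np.max(np.abs(v))):
        raise DegenerateDataError(
            "outcome lies in the span of its controls; residuals are zero"
        )
    return res


def generalized_partial_corr(x, y, controls_x=None, controls_y=None,
                             link_x: str = "linear", link_y: str = "linear",
                             method: str = "taba", omega: float | None = None,
                             residual_type: str = "response",
                             **kwargs) -> CorrelationEstimate:
    """Generalized partial correlation with per-outcome control sets.

    Each outcome is residualized against its own controls through a GLM
    with the requested link (linear, logistic, or Poisson); the residual
    vectors (response residuals by default) are then correlated.  With
    identical control sets and linear links this reduces exactly to
    :func:`partial_corr`; with empty control sets it reduces to the plain
    correlation.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    cx = _controls_matrix(controls_x, xa.size)
    cy = _controls_matrix(controls_y, ya.size)
    rx = _glm_residuals(xa, cx, link_x, residual_type)
    ry = _glm_residuals(ya, cy, link_y, residual_type)
    return correlation(rx, ry, method, omega, **kwargs)


# ---------------------------------------------------------------------------
# I/O and clustering helpers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt", ".tab")) else ","


def read_table(path) -> pd.DataFrame:
    """Read a variables x samples table (CSV, or TSV by extension).

    The first column holds variable ids and the header row sample ids.
    Lines starting with ``#`` are ignored.  Missing values are rejected
    with their coordinates.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        where = [(str(df.index[i]), str(df.columns[j]))
                 for i, j in zip(rows[:10], cols[:10])]
        raise ValueError(f"missing values at {where}; remove or impute first")
    return df


def write_matrix(matrix, path, comments: list[str] | None = None) -> None:
    """Write a PairwiseMatrix or DataFrame as CSV/TSV with ``#`` header
    comments (e.g. the resolved configuration and seed)."""
    df = matrix.values if isinstance(matrix, PairwiseMatrix) else matrix
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep_for(path))


def linkage_from_dist(dist: PairwiseMatrix, method: str = "average"):
    """Hierarchical-clustering linkage on a distance matrix (scipy format).

    Average linkage by default; any scipy linkage criterion may be named.
    Useful for dendrograms/heatmaps of gene dissimilarity.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    if dist.kind != "distance":
        raise ValueError("expected a distance matrix")
    condensed = squareform(dist.values.to_numpy(), checks=False)
    return linkage(condensed, method=method)
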