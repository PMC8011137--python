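"""Independent brute-force oracles used to verify the implementation.

Everything here is written deliberately with explicit loops, Python's
``statistics`` module, and exhaustive enumeration so that it shares no code
path with the package.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np

SN_SMALL_N = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351, 6: 0.993, 7: 1.198,
              8: 1.005, 9: 1.131}
QN_SMALL_N = {2: 0.399, 3: 0.994, 4: 0.512, 5: 0.844, 6: 0.611, 7: 0.857,
              8: 0.669, 9: 0.872}


def brute_sn(values) -> float:
    """O(n^2) double-median Sn with explicit sorting and order statistics."""
    xs = [float(v) for v in values]
    n = len(xs)
    inner = []
    for xi in xs:
        diffs = sorted(abs(xi - xj) for xj in xs)
        inner.append(diffs[(n // 2 + 1) - 1])        # high median
    inner.sort()
    raw = inner[((n + 1) // 2) - 1]                  # low median
    if n <= 9:
        cn = SN_SMALL_N[n]
    elif n % 2 == 1:
        cn = n / (n - 0.9)
    else:
        cn = 1.0
    return 1.1926 * cn * raw


def brute_qn(values) -> float:
    """Qn as the k-th order statistic of all pairwise distances."""
    xs = [float(v) for v in values]
    n = len(xs)
    dists = sorted(abs(a - b) for a, b in itertools.combinations(xs, 2))
    h = n // 2 + 1
    k = h * (h - 1) // 2
    raw = dists[k - 1]
    if n <= 9:
        dn = QN_SMALL_N[n]
    elif n % 2 == 1:
        dn = n / (n + 1.4)
    else:
        dn = n / (n + 3.8)
    return 2.21914 * dn * raw


def robust_zscores(x, y):
    xs = [float(v) for v in x]
    ys = [float(v) for v in y]
    mx, my = statistics.median(xs), statistics.median(ys)
    sx, sy = brute_sn(xs), brute_sn(ys)
    c1 = [(v - mx) / sx for v in xs]
    c2 = [(v - my) / sy for v in ys]
    return c1, c2


def _t(v: float, omega: float) -> float:
    return v / math.cosh(omega * v)


def stepwise_taba(x, y, omega: float) -> float:
    """Hand evaluation of the Taba formula, step by step."""
    c1, c2 = robust_zscores(x, y)
    t1 = [_t(v, omega) for v in c1]
    t2 = [_t(v, omega) for v in c2]
    num = sum(a * b for a, b in zip(t1, t2))
    den = math.sqrt(sum(a * a for a in t1) * sum(b * b for b in t2))
    return num / den


def stepwise_tabwil(x, y, omega: float) -> float:
    """Hand evaluation of the TabWil formula (sum/difference medians)."""
    c1, c2 = robust_zscores(x, y)
    u = [a + b for a, b in zip(c1, c2)]
    v = [a - b for a, b in zip(c1, c2)]
    m1 = statistics.median(abs(w) for w in u)
    m2 = statistics.median(abs(w) for w in v)
    t1, t2 = _t(m1 * m1, omega), _t(m2 * m2, omega)
    return (t1 - t2) / (t1 + t2)


def stepwise_median_corr(x, y) -> float:
    c1, c2 = robust_zscores(x, y)
    m1 = statistics.median(abs(a + b) for a, b in zip(c1, c2))
    m2 = statistics.median(abs(a - b) for a, b in zip(c1, c2))
    return (m1 * m1 - m2 * m2) / (m1 * m1 + m2 * m2)


def midrank(values):
    """Mid-ranks by explicit tie-group averaging."""
    xs = [float(v) for v in values]
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def stepwise_tabwil_rank(x, y, omega: float) -> float:
    return stepwise_tabwil(midrank(x), midrank(y), omega)


def brute_quadrant(x, y) -> float:
    xs = [float(v) for v in x]
    ys = [float(v) for v in y]
    mx, my = statistics.median(xs), statistics.median(ys)
    signs = []
    for a, b in zip(xs, ys):
        prod = (a - mx) * (b - my)
        signs.append(0.0 if prod == 0 else math.copysign(1.0, prod))
    return math.sin(math.pi / 2.0 * (sum(signs) / len(signs)))


def exhaustive_mcd(x, y, h: int) -> float:
    """Global MCD by enumerating every size-h subset (n <= 12)."""
    X = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    best_det, best_cov = math.inf, None
    for comb in itertools.combinations(range(len(X)), h):
        c = np.cov(X[list(comb)], rowvar=False)
        d = c[0, 0] * c[1, 1] - c[0, 1] ** 2
        if d < best_det:
            best_det, best_cov = d, c
    return best_cov[0, 1] / math.sqrt(best_cov[0, 0] * best_cov[1, 1])
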