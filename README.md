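# robustcorr

Robust linear and monotonic correlation estimators for noisy biomedical
data — gene-expression profiles, bioassay readouts, methylation/expression
pairs — where a handful of outlying observations can make the Pearson
correlation report an association that is not there (or hide one that is).

The package implements three bounded-influence correlation estimators
built on the redescending transform

```
T_w(x) = x * sech(w * x)
```

which behaves like the identity near the origin (unit slope at 0) and
returns toward zero as |x| grows, so gross outliers are progressively
discounted. Each variable is first standardized robustly by its median and
the Rousseeuw–Croux Sn scale, `C_i = (x_i - median(X)) / Sn(X)`.

* **Taba** (`taba`, default w = 0.45) — the cosine similarity of
  `T_w(C_1)` and `T_w(C_2)`; a robust analogue of Pearson's r for linear
  association.
* **TabWil** (`tabwil`, default w = 0.05) — with `U = C_1 + C_2`,
  `V = C_1 - C_2`, `m1 = median|U|`, `m2 = median|V|`:
  `r = (T_w(m1^2) - T_w(m2^2)) / (T_w(m1^2) + T_w(m2^2))`; a smoothed,
  bounded variant of the Falk median correlation (its exact w -> 0 limit).
* **TabWil rank** (`tabwil_rank`, default w = 0.05) — TabWil on mid-ranks;
  measures monotonic association, invariant under strictly increasing
  transforms.

Around them the package provides:

* five comparator estimators (Pearson, Spearman, quadrant/sign, median,
  and a bivariate FastMCD correlation) behind one `correlation()` dispatch;
* Fisher-transform confidence intervals with the modified variance
  `(1 + 0.5 r^2)/(n - 3)` and the t test
  `t = r * sqrt((n - 2)/(1 - 0.5 r^2))` on n - 2 df (`fisher_ci`,
  `corr_test`);
* pairwise correlation / distance / p-value matrices over genes x samples
  tables, duplicate-row averaging, hierarchical-clustering linkage, and
  partial / semi-partial / generalized partial correlations with linear,
  logistic, or Poisson residualization (`dissimilarity` module);
* a contamination benchmark: bivariate normal / log-normal / Weibull
  generators, an outlier-injection operator (shift selected points by
  5 SD), bias/RMSE scoring, and frequency-of-lowest tabulation
  (`simulation` module);
* a `robustcorr` CLI with `corr`, `test`, `matrix`, `simulate`, and
  `efficiency` subcommands.

## Worked example

Sixty bivariate normal observations at true correlation 0.7, with three
points pushed 8 SD upward in y:

```python
import numpy as np
from robustcorr import taba, pearson, fisher_ci, corr_test

rng = np.random.default_rng(0)
z = rng.multivariate_normal([0, 0], [[1, .7], [.7, 1]], size=60)
x, y = z[:, 0], z[:, 1].copy()
y[:3] += 8                      # three gross outliers

est = taba(x, y)                # CorrelationEstimate(taba, r=0.670692, n=60, omega=0.45)
pearson(x, y)                   # CorrelationEstimate(pearson, r=0.308849, n=60)
ci = fisher_ci(est)             # IntervalEstimate(lcl=0.4813, ucl=0.8003, level=0.95)
corr_test(est)                  # TestResult(t=5.8018, df=58, p=2.886e-07)
```

Three outliers drag Pearson from ~0.7 down to 0.31; Taba stays at 0.67,
its 95% CI [0.48, 0.80] still covers the true 0.7, and the association
remains clearly significant. The same comparison at scale is what
`robustcorr simulate` quantifies via bias and RMSE.

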