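# Methods

## The estimators

All three robust estimators share one primitive, the redescending
transform `T_w(x) = x * sech(w * x)` with tuning constant `w >= 0`.
`T_w` is odd, has unit derivative at the origin, is bounded for `w > 0`
(maximum at `x* ~ 1.2/w`), and tends to zero as `|x| -> inf`, so an
observation's influence first grows linearly, then saturates, then is
discounted entirely. `w = 0` gives the identity and hence the classical
(non-robust) limit of each estimator.

Variables are standardized robustly before transformation:
`C = (x - median(x)) / Sn(x)`, where Sn is the Rousseeuw–Croux pairwise
double-median scale

```
Sn = c_n * 1.1926 * lowmed_i ( highmed_j |x_i - x_j| )
```

with the high median the `floor(n/2)+1`-th order statistic, the low median
the `floor((n+1)/2)`-th, 1.1926 the consistency constant for the normal
standard deviation, and `c_n` the standard finite-sample correction
(tabulated for n <= 9; `n/(n-0.9)` for odd n > 9; 1 for even n > 9).
Because the formula is commonly cited without being printed in full,
small-sample values from other implementations may differ in the third
decimal if they use a different correction table. The Qn estimator
(first-quartile pairwise distance, constant 2.21914) is available as a
plug-in alternative (`scale="qn"`). Both are computed by the plain O(n^2)
algorithm — sample sizes in this domain are modest — chunked so memory
stays bounded at large n.

**Taba** (default `w = 0.45`) is the cosine similarity of `T_w(C_1)` and
`T_w(C_2)`; `|r| <= 1` by Cauchy–Schwarz, and the estimator is exactly
equivariant under affine maps of either variable (sign-flipping for
negative slopes). **TabWil** (default `w = 0.05`) forms `U = C_1 + C_2`
and `V = C_1 - C_2`, takes `m1 = median|U|`, `m2 = median|V|`, and returns
`(T_w(m1^2) - T_w(m2^2)) / (T_w(m1^2) + T_w(m2^2))`. As `w -> 0` this
converges to the Falk median correlation
`(m1^2 - m2^2)/(m1^2 + m2^2)`, which is also the `median` comparator.
**TabWil rank** is TabWil applied to mid-ranks (ties averaged), hence
invariant under strictly increasing transforms; it measures monotonic
association. The default tuning constants (0.45; 0.05; 0.05) are taken as
given — the efficiency/outlier-tolerance trade-off that produced them is
not re-derived here.

A caveat inherent to the published TabWil form: `T_w` is non-monotone, so
`T_w(m1^2)` is decreasing in `m1` beyond the turning point. We do not
alter the formula; with the default `w = 0.05` and Sn-standardized data
the operating range of `m1^2`, `m2^2` stays below the turning point
(`1/0.05 * 1.2 = 24`) except in pathological inputs.

## Comparators

* `pearson`, `spearman` — textbook definitions (Spearman = Pearson on
  mid-ranks).
* `quadrant` — sign correlation `sin(pi/2 * mean sign[(x - med x)(y - med y)])`;
  the sine transform makes it consistent for rho under bivariate
  normality. Points exactly at a median contribute zero sign.
* `median` — the Falk estimator above, standardized by Sn for internal
  consistency with TabWil.
* `mcd` — correlation read off the bivariate minimum covariance
  determinant scatter: `h = floor((n + 3)/2)` by default, 500 random
  3-point elemental starts refined by concentration steps (all starts
  iterated simultaneously with closed-form 2x2 inverses) until the
  determinant stops decreasing; the raw (non-reweighted) covariance of the
  best h-subset is used, and the search is deterministic given its seed.
  For n <= 12 the search provably matches exhaustive subset enumeration in
  the test suite; an exactly singular h-subset (exact fit) yields r = ±1.

Estimates below n = 4 are refused (df = n - 2 >= 2 is needed for
inference, and robust scales need headroom beyond n = 2). A zero robust
scale (more than half the values tied) raises an explicit error rather
than returning NaN, so non-finite values never propagate into distance
matrices.

## Inference

The confidence interval applies the Fisher transform `F = arctanh(r)` with
the modified variance `(1 + 0.5 r^2)/(n - 3)` appropriate for robust
correlation measures, and back-transforms by tanh; one-sided limits
replace `alpha/2` by `alpha`. The test statistic is
`t = r * sqrt((n - 2)/(1 - 0.5 r^2))` with n - 2 df; p-values use the t
distribution (the statistic stays finite at |r| = 1, unlike the classical
Pearson t). At |r| = 1 the interval degenerates to [r, r] with a warning,
keeping downstream matrices finite.

Calibration, measured by this package's own simulation: the 95% interval
for Taba on bivariate normal data (rho = 0.5, n = 100) covers at ~0.96,
and the test's type-I error at rho = 0, n = 50 is ~0.04. The same t
statistic applied to TabWil and TabWil rank over-rejects badly (~0.21 and
~0.27 at nominal 0.05): their null sampling variance is ~2.3x and ~3.2x
Pearson's 1/n (the median-based construction has low efficiency), while
the statistic's normalization implicitly assumes Pearson-like variance.
The test is provided for all three estimators as published; treat its
p-values for the TabWil pair as anti-conservative at moderate n.

## Dissimilarity matrices and partial correlations

Inputs are variables x samples tables (rows = genes). Duplicate-id rows
may be collapsed by arithmetic mean (`average_duplicates`); missing values
are rejected with coordinates rather than silently dropped. Matrices are
computed on the upper triangle and mirrored, so symmetry is exact.

The default distance is `d = (1 - r)/2`: for column-standardized vectors
this is the convention under which `d_Euclid = 2 sqrt(n * d_Pearson)`
holds identically, which ties correlation-based clustering to Euclidean
geometry; `1 - r` and `1 - |r|` are selectable. The p-value matrix has a
zero diagonal by convention, excluded from the optional (off by default)
Benjamini–Hochberg adjustment. `linkage_from_dist` delegates to scipy
hierarchical clustering, average linkage by default; note that cluster
memberships are identical under `(1 - r)/2` and `1 - r` for monotone
linkage criteria, only heights differ.

Partial correlation residualizes both outcomes on the controls by OLS
(with intercept) and correlates the residuals with any estimator;
semi-partial residualizes one side. The generalized form fits a GLM per
outcome (linear/logistic/Poisson, own controls per side, statsmodels) and
correlates response residuals (observed minus fitted mean); Pearson and
deviance residuals are selectable. With identical controls and linear
links it reduces exactly to the partial correlation; with empty controls,
to the plain one.

## Simulation benchmark

The benchmark draws m replicate pairs per design cell from

* bivariate normal, mean (0,0), covariance [[1, rho], [rho, 1]];
* bivariate log-normal: componentwise exp of a bivariate normal with mean
  (1, 3) and that same covariance on the log scale (the parameterization
  of the common generator packages; absolute bias values — not method
  orderings — are sensitive to this reading);
* bivariate Weibull: Gaussian copula at latent correlation rho with
  Weibull(shape 1.5, scale 1) marginals. rho is nominal (the latent
  normal's correlation) and scores are computed against it.

Contamination selects `round(fraction * n)` points without replacement
and adds `sign * multiplier * SD` to each coordinate (both coordinates by
default — a bivariate outlier — with x-only/y-only flags for sensitivity
analysis), where SD is the classical sample standard deviation (ddof = 1)
of the uncontaminated draw; defaults are multiplier 5, positive shift.
Scores per method are `bias = |mean(rhohat) - rho|` and
`RMSE = sqrt(mean (rhohat - rho)^2)`; RMSE >= bias always. Every method
sees the identical contaminated sample within a replicate; per-replicate
streams are spawned from the master seed, so scoreboards are bit-identical
across reruns. `frequency_of_lowest` tabulates, over a full factorial
(distributions x rho in {0, .2, .5, .7, .9} x n in {20, 40, 80, 160, 320}
x contamination in {0, 5%, 10%}), how often each method attains the lowest
bias or RMSE per stratum, crediting all exactly tied methods.

Relative efficiency is defined as the finite-sample variance ratio
`var(Pearson)/var(method)` over independent clean bivariate normal draws —
a Monte-Carlo stand-in for asymptotic efficiency. Note this is not the
Pitman (efficacy-based) efficiency: for Spearman at rho = 0 the variance
ratio is ~(n-1)/n ~ 1, whereas the Pitman value is 9/pi^2 ~ 0.91. For
Taba at the default tuning constant the variance ratio is rho-dependent:
~0.98 at rho = 0, ~0.92 at rho = 0.5, declining toward ~0.78 at
rho = 0.9 — the symmetric redescending transform costs more information
as the point cloud concentrates along the diagonal. The "over 95%
efficiency under normality" characterization of the default constant
therefore holds near independence.

## Problem sizes used by the test suite

Scaled-down designs chosen as representative while keeping the suite
quick: robustness orderings at m = 500, n = 40, 10% contamination (all
three distributions); CI coverage at 2000 replicates; type-I error at
5000; efficiency at 2000 replicates of n = 500; Sn consistency at
n = 2000 over 80 replicates (mean within 3% of the normal sigma). The
full published-scale factorial (m = 5000 per cell, 225 cells, eight
methods) is runnable through `robustcorr simulate` but is not exercised
by the tests; at desk scale only the qualitative orderings are asserted,
not frequency-of-lowest counts, which are unstable under Monte-Carlo
error at small m.

## What the generators do and do not emulate

The synthetic designs emulate elliptical (normal) and skewed
(log-normal, Weibull) bivariate dependence with point-mass outlier
contamination at a fixed shift. They do not emulate heavy-tailed
marginals without contamination (e.g. t distributions), asymmetric or
leverage-style contamination, dependent outliers, or the
mean–variance coupling of count-based expression data. Passing tests
demonstrate correctness of the implementations and the stated orderings
under these designs, not performance guarantees on any particular real
dataset.

## Known limitations

* The MCD search is heuristic beyond tiny n (as is FastMCD); 500 starts
  make disagreement with the global optimum negligible at the benchmark's
  sample sizes but it is not certified.
* The t test's nominal level is reliable for Taba only (see Inference).
* TabWil/TabWil rank take values on a coarse grid for small n (medians of
  small sets), so their sampling distribution is discrete at n < ~20.
* Weibull dependence is copula-based; a different multivariate-Weibull
  construction would change absolute bias/RMSE values, though not the
  contamination orderings.
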