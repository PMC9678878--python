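# Methods

## Model and assumptions

All estimators in this package derive from one probabilistic fact. Treat
the data `X = {x_i}` as a realization of a Poisson point process with
locally constant density on a manifold of dimension `d`, and let `r_{i,l}`
be the distance from `x_i` to its `l`-th nearest neighbor (1-based; the
point itself is order 0 with `r_{i,0} = 0`). Then the volumes of the
hyperspherical shells between consecutive neighbors,
`v_{i,l} = ω_d (r_{i,l}^d − r_{i,l−1}^d)` with `ω_d` the unit-ball volume,
are i.i.d. exponential. Everything else is algebra on Gamma variables:

- consecutive ratios `μ_{i,l} = r_{i,l}/r_{i,l−1}` are
  `Pareto(1, (l−1)d)`, jointly independent across `l` for fixed `i`;
- the generalized ratio `μ̇ = r_{i,n2}/r_{i,n1}` satisfies
  `μ̇^{−d} ~ Beta(n1, n2−n1)`, which yields the closed-form density,
  the CDF used for Kolmogorov–Smirnov checks, the moment formula
  `E[μ̇^k] = B(n2−n1, n1−k/d)/B(n2−n1, n1)` (finite iff `n1·d > k`), and
  the two-Gamma sampler `μ̇ = (1 + G_{n2−n1}/G_{n1})^{1/d}`.

Homogeneity only needs to hold out to the largest neighbor distance an
estimator touches (`r_2` for TWO-NN, `r_L` for MG, `r_{n2}` for Gride) —
"local homogeneity". Independence of ratios **across** points `i` is an
approximation: nearby points share neighbors, and the sharing grows with
the neighbor order relative to the sample size. This is why MG (which uses
every consecutive ratio up to `L`) degrades faster than Gride (which uses a
single ratio per point) as neighborhoods grow.

## Estimators

| method | statistic | point estimate | interval |
|---|---|---|---|
| `twonn_ls` | sorted `log μ` vs `−log(1−F̃)` | no-intercept LS slope | none |
| `twonn_mle` | `Σ log μ_i` | `(n−1)/Σ log μ_i` | exact pivot `d̂/d ~ IG(n, n−1)` |
| `twonn_bayes` | `Σ log μ_i` | posterior mean of `Gamma(a+n, b+Σ log μ)` | equal-tailed credible |
| `gride_mle` | `{μ̇_i}` | root of the concave score | parametric bootstrap percentile |
| `mg_mle` | `Σ_i Σ_l (l−1) log μ_{i,l}` | `(n(L−1)−1)/denominator` | pivot with `n(L−1)` terms |
| `mg_bayes` | same | posterior mean | equal-tailed credible |
| `lb` | per-order `S_{i,k} = Σ_{j<k} log(r_k/r_j)` | average of `m̂_k` (or corrected `m̂'_k`) over `k = q1..q2` | none |
| `moments` | sample mean of `μ̇` | monotone inversion of the mean formula | none |

Numerical choices:

- **Log-space arithmetic everywhere.** `log(μ^d − 1)` is computed as
  `d log μ + log1p(−exp(−d log μ))`, and all Beta functions as log-Gamma
  differences, so orders in the thousands (the benchmark uses
  `n2 = 1500`) stay finite.
- **Gride optimization.** The score is strictly decreasing in `d`
  (concavity of the log-likelihood, spot-checked in the tests), so the MLE
  is found by `brentq` on an expanding bracket inside `(10⁻³, 10³)`. The
  domain deliberately extends below 1: strongly noise-dominated or
  coarse-scale data legitimately produce `d̂ < 1` (the benchmark spiral
  yields 0.997 at orders (750, 1500)), and the likelihood remains concave
  for every `d > 0`. For consecutive orders (`n2 = n1 + 1`) the closed
  form `n/(n1 Σ log μ̇)` is used, which makes the identity
  `gride(1,2) · (n−1)/n = twonn_mle` exact.
- **Bootstrap.** Parametric: resample `n` ratios from the fitted law,
  re-maximize, take percentile quantiles. The CLI default is 5000
  resamples; the library requires an explicit seed whenever resampling is
  requested. Percentile intervals are clipped to contain the point
  estimate (relevant only at tiny `n`).
- **Empirical CDF convention** for the least-squares variant:
  `F̃(μ_(i)) = i/n`; the `i = n` pair is always dropped (infinite
  ordinate), and the default trim keeps the lowest 90% of ratios — the
  largest ratios are the ones most likely to violate local homogeneity.
- **Priors.** `a = b = 1` by default for the Bayesian variants —
  a weakly-informative choice centered at 1 with variance 1, overridable;
  the point estimate is the posterior mean (the quantile function is
  exposed for medians).
- **Moment validity** is enforced as `n1·d > k` — the `n1`-dependent
  generalization of the familiar `d > k` Pareto condition, which is the
  worst case `n1 = 1`.
- **Support boundary.** The ratio density is declared 0 at `μ̇ = 1` even
  for consecutive orders where the right limit is positive (`n1·d`); a
  measure-zero convention.

## Neighbor computation

Exact search only (scikit-learn brute force, or tree backends when the
requested order is small relative to `n`); approximate indices are
excluded by design because ratio statistics are sensitive to rank swaps at
small distances. Ties between equidistant neighbors are broken by original
row index — an arbitrary but deterministic convention. Duplicate rows make
`r_{i,1} = 0` and ratios infinite, so they are a hard error naming the
offending rows, with an opt-in `duplicates="drop"` policy; silent jitter
would corrupt the likelihoods. The metric is a parameter (Euclidean
default). `generalized_ratios(..., subset=...)` restricts the likelihood
to a subset of *center* points while neighbors are still found in the full
configuration — used to estimate on the core of a pivot-centered
configuration where every retained point has complete neighborhoods.

## Scale analysis

Two protocols produce a `ScaleProfile` over a growing neighborhood, both
reporting the mean distance to the outermost neighbor order used as the
scale coordinate (log-transformed only at presentation time):

- **Gride order sweep** (`gride_scan`): `n2 = ratio · n1` (ratio 2 by
  default, the setting that trades scalability against scale resolution
  best in our experience), `n1` doubling geometrically from 1. The sweep
  never subsamples — that is the point of the method.
- **TWO-NN decimation** (`twonn_decimation_scan`): keep a fraction `c`,
  re-fit, average over replicas. Subsampling is without replacement;
  replicas are independently seeded and may overlap in content. With more
  than one replica the profile carries a ±2-standard-error band across
  replicas; with one replica, the analytic interval.

## Synthetic generators

Each generator returns the data matrix plus a spec (generator, parameters,
seed, true id) that is also written as a JSON sidecar by `simulate`.

- **spiral** — one free parameter `u0` on an evenly spaced grid over
  `[1/(4π), S̄]` (both endpoints included; the grid convention matters
  only at order 1/n), `u = 2π√u0`, `x = u cos(u+2π)`, `y = u sin(u+2π)`,
  `z = x² + y²`, then *independent* Gaussian noise with standard
  deviations `(σx, σy, σz)` per coordinate (defaults 0.5, 0.5, 1). True
  id 1. Note that without noise the even grid is a pathological input for
  first/second-neighbor ratios: consecutive spacings are nearly equal, so
  `r_2/r_1 ≈ 1` and TWO-NN diverges; ratios of moderate orders recover 1.
- **gaussian** — standard `d`-variate Gaussian in the first `d` of `D`
  coordinates (`D = d+5` default), plus i.i.d. `N(0, σ²)` on all `D`
  coordinates. The "orthogonal noise" experiments are the special cases
  `D = d + 1` and `D = d + 20`.
- **hypercube** — uniform on `[0,1]^d`.
- **swissroll** — the standard `(t cos t, h, t sin t)` strip embedding
  (delegated to scikit-learn; the mapping is a literature convention).
- **radial** — the exact model: shell volumes i.i.d. `Exponential(ρ)`,
  radii `r_l = (Σ_{j≤l} v_j / ω_d)^{1/d}` around a pivot at the origin,
  directions uniform on the sphere (uniform angle at `d = 2`, normalized
  Gaussians above, random sign at `d = 1`). Rows are ordered by radius,
  so the first `j` rows are the `j` points nearest the pivot.

### What the generators do and do not emulate

They reproduce the simulation conditions the estimators were designed and
validated under: exact ground-truth dimension, controlled noise,
homogeneous sampling. They do **not** contain density gradients, multiple
manifolds with different dimensions, heavy-tailed noise, or discrete/
quantized features — all common in real data. Passing the recovery suite
therefore demonstrates correctness of the statistical machinery under its
stated assumptions, not robustness to every violation real datasets
exhibit; the scale profiles are the diagnostic tool for the latter.

## Problem sizes in the test suite

The statistical suite runs at sizes chosen to keep Monte-Carlo error
comfortably below the asserted tolerances while remaining quick on a
single CPU: 20 noise realizations of the n=5000 benchmark spiral, 2000
pivot-law replicas at n=500, 200 radial configurations at n=8192 (with the
estimate restricted to the 2048-point core, see below), 200 MG replicas at
n=5000, L=10, and 30 noisy-cloud replicas at n=1000. All simulations use
fixed seeds.

Radial recovery is evaluated on the configuration core because points near
the outer boundary of a finite radial sample have truncated neighborhoods
(their true high-order neighbors were never generated), which biases
high-order estimates downward; restricting the likelihood to center points
with complete neighborhoods isolates the estimator property being tested —
the small correlation-induced bias at order 1 that vanishes at higher
orders.

## Known limitations

- A fully Bayesian treatment of the generalized-ratio likelihood (beyond
  the conjugate TWO-NN/MG cases) is not provided; the Lomax posterior
  predictive sampler supports goodness-of-fit simulation only.
- The joint law of the first `L` neighbor distances is not implemented.
- No automatic plateau detection on scale profiles: choosing the scale at
  which to read off the id remains a visual/diagnostic step.
- Decimation estimates at very small `c` rest on a handful of points and
  are reported with correspondingly wide bands; they are kept because the
  comparison against order sweeps is instructive, not because they are
  recommended.
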