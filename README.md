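# gride-id

Likelihood-based intrinsic-dimension (id) estimation from nearest-neighbor
distance ratios: **TWO-NN**, **Gride** (generalized-ratio estimator), **MG**
(consecutive-ratio pooling, the corrected Levina–Bickel estimator), and
**LB**, with exact and bootstrap uncertainty quantification, scale-dependent
id profiling, and synthetic-manifold generators with known ground truth.

## Who this is for

Practitioners of high-dimensional data analysis (omics, single-cell,
imaging, ML embeddings) who need the number of effective degrees of freedom
of a dataset — and, crucially, how that number depends on the *scale* at
which the data are examined. Short-scale measurement noise inflates the id;
the estimators here let you sweep the neighborhood size and watch the
estimate relax to the manifold's dimension.

## The model

For a homogeneous Poisson process on a `d`-dimensional manifold, the volume
of the hyperspherical shell between consecutive neighbors of a point is
exponential. Consequences, writing `r_{i,l}` for the distance from point
`i` to its `l`-th nearest neighbor:

- `μ_i = r_{i,2}/r_{i,1} ~ Pareto(1, d)` — the TWO-NN law, giving the
  unbiased MLE `d̂ = (n−1)/Σ log μ_i` with the exact pivot
  `d̂/d ~ InvGamma(n, n−1)` for confidence intervals;
- `μ_{i,l} = r_{i,l}/r_{i,l−1} ~ Pareto(1, (l−1)d)`, jointly independent in
  `l` — pooling orders `2..L` gives the closed-form MG estimator
  `d̂_L = (n(L−1)−1)/Σ_i Σ_l (l−1) log μ_{i,l}` with variance
  `d²/(n(L−1)−2)`;
- the generalized ratio `μ̇ = r_{i,n2}/r_{i,n1}` has density
  `f(μ̇) = d (μ̇^d − 1)^{n2−n1−1} / (μ̇^{(n2−1)d+1} B(n2−n1, n1))` for
  `μ̇ > 1` — **Gride**. Its log-likelihood is concave in `d`; the MLE is a
  score root, intervals come from a parametric bootstrap. Raising
  `(n1, n2)` (we default to `n2 = 2 n1`) enlarges the neighborhood *without
  discarding data*, which is what makes Gride robust to short-scale noise.

## Worked example

```python
import numpy as np
from gride import (build_neighbor_table, generalized_ratios,
                   twonn_mle, gride_mle, make_spiral)

# a 3-D spiral with one true degree of freedom, blurred by noise
x, spec = make_spiral(n=5000, s_bar=1.0, sigma_x=0.5, sigma_y=0.5,
                      sigma_z=1.0, seed=0)
table = build_neighbor_table(x, kmax=1500)

print(twonn_mle(generalized_ratios(table, 1, 2)).d_hat)        # 3.129
print(gride_mle(generalized_ratios(table, 2, 4)).d_hat)        # 3.033
print(gride_mle(generalized_ratios(table, 250, 500)).d_hat)    # 1.563
print(gride_mle(generalized_ratios(table, 750, 1500)).d_hat)   # 0.998
```

At the smallest scales the noise makes the spiral look 3-dimensional
(TWO-NN ≈ 3.0); as the neighbor orders grow, Gride sweeps past the noise
and converges to the curve's true dimension 1 — all on the full dataset.

The same analysis from the shell:

```
gride simulate spiral --n 5000 --seed 0 --output spiral.csv
gride estimate spiral.csv --method twonn-mle
gride scan spiral.csv --output profile.tsv
```

`estimate` prints a JSON record (`d_hat`, `ci_low`, `ci_high`, orders,
scale, seed); `scan` writes a TSV profile of the estimate across a
geometrically doubling order schedule.

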