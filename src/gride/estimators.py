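"""Intrinsic-dimension estimators built on neighbor-distance ratios.

Implemented families:

* **TWO-NN** — ratios of second to first neighbor distances are
  ``Pareto(1, d)``; estimated by least squares on the linearized CDF
  (the original recipe), by maximum likelihood with an exact
  Inverse-Gamma pivot for confidence intervals, or conjugately in a
  Bayesian setting.
* **Gride** — ratios of two neighbors of generic orders ``(n1, n2)``;
  the log-likelihood is concave in ``d`` and maximized by a root of the
  score; confidence intervals by parametric bootstrap.
* **MG** — closed-form MLE pooling all consecutive ratios up to order
  ``L`` (equivalent to the corrected Levina-Bickel estimator), with the
  same Inverse-Gamma pivot on ``n(L-1)`` effective terms.
* **LB** — the original Levina-Bickel average and its corrected
  ("averaged MG") variant over a range of neighbor orders.
* a method-of-moments inversion of the generalized-ratio mean.

The exact pivot used throughout is ``d_hat / d ~ InvGamma(N, N - 1)``
where ``N`` is the number of independent log-ratio terms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, special, stats

from .distributions import (
    GammaPosterior,
    GrideLaw,
    pareto_fit_quantities,
    sample_gride_ratio,
)
from .errors import (
    BoundaryRatioError,
    DataError,
    DegenerateRatiosError,
    InsufficientDataError,
    NumericError,
    ParameterError,
)
from .neighbors import ConsecutiveRatios, NeighborTable, RatioSample, generalized_ratios

__all__ = [
    "IdEstimate",
    "twonn_mle",
    "twonn_ls",
    "twonn_bayes",
    "gride_mle",
    "gride_loglik",
    "gride_score",
    "mg_mle",
    "mg_bayes",
    "lb_estimator",
    "moment_estimator",
]

# optimization domain for d: wider than [1, inf) because noisy or strongly
# decimated data can legitimately push the maximizer below 1 while the
# likelihood stays concave for every d > 0
_D_MIN, _D_MAX = 1e-3, 1e3


@dataclass
class IdEstimate:
    """A point estimate of the intrinsic dimension with optional interval.

    Attributes
    ----------
    method : str
        One of ``twonn_ls, twonn_mle, twonn_bayes, gride_mle, mg_mle,
        mg_bayes, lb, moments``.
    d_hat : float
        Point estimate.
    ci_low, ci_high : float or None
        Interval bounds at ``level`` (confidence or credible, per method).
    n_effective : int
        Number of independent likelihood terms.
    n1, n2, L : int or None
        Neighbor orders used, when applicable.
    scale : float or None
        Mean distance to the outermost neighbor order used.
    seed : int or None
        Seed of any resampling involved (bootstrap).
    """

    method: str
    d_hat: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None
    n_effective: int = 0
    n1: int | None = None
    n2: int | None = None
    L: int | None = None
    scale: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (0 < self.ci_low <= self.ci_high):
                raise NumericError(
                    f"invalid interval [{self.ci_low}, {self.ci_high}]"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_level(level: float) -> None:
    if not (0.0 < level < 1.0):
        raise ParameterError(f"interval level must be in (0, 1), got {level}")


def _invgamma_pivot_interval(d_hat: float, n_terms: int, level: float):
    """CI from the exact pivot d_hat/d ~ InvGamma(N, N-1)."""
    alpha = 1.0 - level
    pivot = stats.invgamma(a=n_terms, scale=n_terms - 1)
    return d_hat / pivot.ppf(1.0 - alpha / 2.0), d_hat / pivot.ppf(alpha / 2.0)


# ---------------------------------------------------------------------------
# TWO-NN family
# ---------------------------------------------------------------------------


def twonn_mle(ratios: RatioSample, level: float = 0.95, scale: float | None = None) -> IdEstimate:
    """Unbiased TWO-NN maximum-likelihood estimate ``(n-1) / sum(log mu)``.

    Requires the second-to-first neighbor ratios (``n1=1, n2=2``); the
    confidence interval uses the exact Inverse-Gamma pivot.
    """
    _check_level(level)
    _require_orders(ratios, 1, 2)
    s, n = pareto_fit_quantities(ratios.log())
    if n < 3:
        raise InsufficientDataError(f"need at least 3 ratios, got {n}")
    if s <= 0:
        raise DegenerateRatiosError("all ratios equal 1: sum of log-ratios is zero")
    d_hat = (n - 1) / s
    lo, hi = _invgamma_pivot_interval(d_hat, n, level)
    return IdEstimate(
        method="twonn_mle", d_hat=d_hat, ci_low=lo, ci_high=hi, level=level,
        n_effective=n, n1=1, n2=2, scale=scale,
    )


def twonn_ls(ratios: RatioSample, trim: float = 0.90, scale: float | None = None) -> IdEstimate:
    """Least-squares TWO-NN fit on the linearized Pareto CDF.

    Sorts the ratios, pairs ``log mu_(i)`` with ``-log(1 - F~(mu_(i)))``
    where ``F~(mu_(i)) = i/n`` is the empirical CDF, drops the top
    ``1 - trim`` fraction (the largest ratios typically violate local
    homogeneity; the ``i = n`` point is always dropped since its ordinate
    is infinite), and returns the no-intercept regression slope.
    """
    if not (0.0 < trim <= 1.0):
        raise ParameterError(f"trim must be in (0, 1], got {trim}")
    _require_orders(ratios, 1, 2)
    s, n = pareto_fit_quantities(ratios.log())  # validates ordering
    mu = np.sort(ratios.values)
    i = np.arange(1, n + 1)
    keep = min(int(np.floor(trim * n)), n - 1)
    if keep < 3:
        raise InsufficientDataError(
            f"trim={trim} leaves {keep} pairs; at least 3 are required"
        )
    x = np.log(mu[:keep])
    y = -np.log1p(-i[:keep] / n)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateRatiosError("all retained ratios equal 1")
    d_hat = float(x @ y) / sxx
    return IdEstimate(
        method="twonn_ls", d_hat=d_hat, n_effective=keep, n1=1, n2=2, scale=scale,
    )


def twonn_bayes(
    ratios: RatioSample,
    prior_shape: float = 1.0,
    prior_rate: float = 1.0,
    level: float = 0.95,
    scale: float | None = None,
) -> tuple[GammaPosterior, IdEstimate]:
    """Conjugate Bayesian TWO-NN: ``Gamma(a + n, b + sum(log mu))`` posterior.

    Returns the posterior together with an estimate whose point value is
    the posterior mean and whose interval is equal-tailed at ``level``.
    """
    _check_level(level)
    if prior_shape <= 0 or prior_rate <= 0:
        raise ParameterError("prior shape and rate must be positive")
    _require_orders(ratios, 1, 2)
    s, n = pareto_fit_quantities(ratios.log())
    post = GammaPosterior(shape=prior_shape + n, rate=prior_rate + s)
    lo, hi = post.interval(level)
    est = IdEstimate(
        method="twonn_bayes", d_hat=post.mean(), ci_low=lo, ci_high=hi,
        level=level, n_effective=n, n1=1, n2=2, scale=scale,
    )
    return post, est


def _require_orders(ratios: RatioSample, n1: int, n2: int) -> None:
    if (ratios.n1, ratios.n2) != (n1, n2):
        raise ParameterError(
            f"estimator requires ratios of orders ({n1}, {n2}), "
            f"got ({ratios.n1}, {ratios.n2})"
        )


# ---------------------------------------------------------------------------
# Gride
# ---------------------------------------------------------------------------


def gride_loglik(d, ratios: RatioSample):
    """Generalized-ratio log-likelihood as a function of ``d``."""
    n1, n2 = ratios.n1, ratios.n2
    log_mu = ratios.log()
    d = np.asarray(d, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    n = log_mu.size
    out = np.empty(d.shape)
    for j, dj in enumerate(d):
        # log(mu^d - 1) = d log mu + log1p(-exp(-d log mu)); requires mu > 1
        log_pow = dj * log_mu + np.log1p(-np.exp(-dj * log_mu))
        out[j] = (
            n * np.log(dj)
            + (n2 - n1 - 1) * log_pow.sum()
            - n * special.betaln(n2 - n1, n1)
            - ((n2 - 1) * dj + 1.0) * log_mu.sum()
        )
    return float(out[0]) if scalar else out


def gride_score(d: float, ratios: RatioSample) -> float:
    """Derivative of the Gride log-likelihood in ``d`` (strictly decreasing)."""
    n1, n2 = ratios.n1, ratios.n2
    log_mu = ratios.log()
    n = log_mu.size
    # mu^d log mu / (mu^d - 1) = log mu / (1 - mu^-d), stable for large d
    c = n2 - n1 - 1
    extra = c * float(np.sum(log_mu / (-np.expm1(-d * log_mu)))) if c else 0.0
    return n / d + extra - (n2 - 1) * float(log_mu.sum())


def gride_mle(
    ratios: RatioSample,
    level: float = 0.95,
    bootstrap_reps: int = 0,
    seed: int | None = None,
    scale: float | None = None,
) -> IdEstimate:
    """Gride maximum-likelihood estimate for generic neighbor orders.

    The log-likelihood is concave in ``d``, so the MLE is the unique root
    of the score, found by bracketed root-finding over ``(1e-3, 1e3)``.
    For consecutive orders (``n2 = n1 + 1``) the Pareto closed form
    ``n / (n1 * sum(log mu))`` is used directly.

    Confidence intervals (optional) are percentile intervals over
    ``bootstrap_reps`` parametric resamples drawn from the fitted law;
    ``seed`` is required when ``bootstrap_reps > 0``.
    """
    _check_level(level)
    n1, n2 = ratios.n1, ratios.n2
    log_mu = ratios.log()
    s, n = pareto_fit_quantities(log_mu)
    if s <= 0:
        raise DegenerateRatiosError("all ratios equal 1")
    if n2 - n1 >= 2 and np.any(log_mu <= 0):
        raise BoundaryRatioError(
            "ratio equal to 1 with n2 - n1 >= 2: log(mu^d - 1) is undefined; "
            "screen duplicate or coincident neighbors first"
        )
    d_hat = _gride_root(ratios)
    lo = hi = None
    used_seed = None
    if bootstrap_reps:
        if seed is None:
            raise ParameterError("seed is required for the parametric bootstrap")
        used_seed = int(seed)
        rng = np.random.default_rng(used_seed)
        law = GrideLaw(d=d_hat, n1=n1, n2=n2)
        reps = np.empty(bootstrap_reps)
        for b in range(bootstrap_reps):
            mu_b = sample_gride_ratio(law, n, rng)
            reps[b] = _gride_root(RatioSample(values=mu_b, n1=n1, n2=n2))
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        # percentile intervals are not anchored at the point estimate; clip
        # pathological tiny-n cases so the invariant lo <= d_hat <= hi holds
        lo, hi = min(lo, d_hat), max(hi, d_hat)
    return IdEstimate(
        method="gride_mle", d_hat=d_hat, ci_low=lo, ci_high=hi,
        level=level if bootstrap_reps else None, n_effective=n,
        n1=n1, n2=n2, scale=scale, seed=used_seed,
    )


def _gride_root(ratios: RatioSample) -> float:
    n1, n2 = ratios.n1, ratios.n2
    log_mu = ratios.log()
    if n2 - n1 == 1:
        # score reduces to n/d - n1 * sum(log mu) = 0
        return log_mu.size / (n1 * float(log_mu.sum()))
    lo, hi = _D_MIN, 8.0
    f_lo = gride_score(lo, ratios)
    if f_lo < 0:
        raise NumericError("score negative at the lower bracket; data degenerate")
    while gride_score(hi, ratios) > 0:
        hi *= 2.0
        if hi > _D_MAX:
            raise NumericError(
                f"score still positive at d = {_D_MAX}: estimate out of range"
            )
    return float(optimize.brentq(gride_score, lo, hi, args=(ratios,), xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# MG (consecutive-ratio pooling) and LB
# ---------------------------------------------------------------------------


def mg_mle(cons: ConsecutiveRatios, level: float = 0.95, scale: float | None = None) -> IdEstimate:
    """Closed-form MG estimate pooling consecutive ratios up to order ``L``.

    ``d_hat = (n(L-1) - 1) / sum_i sum_l (l-1) log mu_{i,l}``; the
    Inverse-Gamma pivot applies with ``n(L-1)`` effective terms, and the
    theoretical variance is ``d^2 / (n(L-1) - 2)`` — smaller than TWO-NN's,
    at the price of a wider homogeneity requirement (up to ``r_L``).
    Reduces to the TWO-NN MLE at ``L = 2``.
    """
    _check_level(level)
    denom = cons.weighted_log_sum()
    if not np.isfinite(denom):
        raise DataError("non-finite log-ratios in the consecutive-ratio matrix")
    if denom <= 0:
        raise DegenerateRatiosError("weighted log-ratio sum is zero")
    n_terms = cons.n * (cons.L - 1)
    d_hat = (n_terms - 1) / denom
    lo, hi = _invgamma_pivot_interval(d_hat, n_terms, level)
    return IdEstimate(
        method="mg_mle", d_hat=d_hat, ci_low=lo, ci_high=hi, level=level,
        n_effective=n_terms, L=cons.L, scale=scale,
    )


def mg_bayes(
    cons: ConsecutiveRatios,
    prior_shape: float = 1.0,
    prior_rate: float = 1.0,
    level: float = 0.95,
    scale: float | None = None,
) -> tuple[GammaPosterior, IdEstimate]:
    """Conjugate Bayesian MG: ``Gamma(a + n(L-1), b + weighted log sum)``."""
    _check_level(level)
    if prior_shape <= 0 or prior_rate <= 0:
        raise ParameterError("prior shape and rate must be positive")
    denom = cons.weighted_log_sum()
    if not np.isfinite(denom) or denom < 0:
        raise DataError("invalid weighted log-ratio sum")
    n_terms = cons.n * (cons.L - 1)
    post = GammaPosterior(shape=prior_shape + n_terms, rate=prior_rate + denom)
    lo, hi = post.interval(level)
    est = IdEstimate(
        method="mg_bayes", d_hat=post.mean(), ci_low=lo, ci_high=hi,
        level=level, n_effective=n_terms, L=cons.L, scale=scale,
    )
    return post, est


def lb_estimator(
    table: NeighborTable,
    q1: int = 10,
    q2: int = 20,
    corrected: bool = False,
    scale: float | None = None,
) -> IdEstimate:
    """Levina-Bickel estimator averaged over neighbor orders ``q1..q2``.

    For each order ``k`` the per-point statistic is
    ``S_{i,k} = sum_{j<k} log(r_{i,k}/r_{i,j})``.  The original estimator
    averages inverses, ``m_k = (k-1)/n * sum_i 1/S_{i,k}``; the corrected
    variant (``corrected=True``, the averaged-MG form) inverts the average,
    ``m'_k = n(k-1) / sum_i S_{i,k}``.  The reported value is the mean of
    ``m_k`` (or ``m'_k``) over ``k = q1..q2``; no analytic interval exists.
    """
    if not (2 <= q1 <= q2):
        raise ParameterError(f"need 2 <= q1 <= q2, got ({q1}, {q2})")
    table._check_order(q2)
    log_r = np.log(table.distances)
    cum = np.concatenate(
        [np.zeros((table.n, 1)), np.cumsum(log_r, axis=1)], axis=1
    )  # cum[:, k] = sum of first k log-distances
    estimates = np.empty(q2 - q1 + 1)
    for j, k in enumerate(range(q1, q2 + 1)):
        s_ik = (k - 1) * log_r[:, k - 1] - cum[:, k - 1]  # sum_{j<k} log(r_k/r_j)
        if np.any(s_ik <= 0):
            raise DegenerateRatiosError(
                f"zero log-ratio sum at order k={k}; screen duplicates first"
            )
        if corrected:
            estimates[j] = table.n * (k - 1) / float(s_ik.sum())
        else:
            estimates[j] = (k - 1) / table.n * float((1.0 / s_ik).sum())
    return IdEstimate(
        method="lb", d_hat=float(estimates.mean()), n_effective=table.n,
        n1=q1, n2=q2, scale=scale,
    )


# ---------------------------------------------------------------------------
# method of moments
# ---------------------------------------------------------------------------


def moment_estimator(ratios: RatioSample, scale: float | None = None) -> IdEstimate:
    """Invert the generalized-ratio mean ``B(n2-n1, n1-1/d)/B(n2-n1, n1)``.

    The theoretical mean decreases monotonically from infinity (at
    ``d -> 1/n1``) to 1 (as ``d -> inf``), so a sample mean above 1 pins a
    unique ``d``, found by bracketed root-finding.  Means at or below 1, or
    so close to 1 that ``d`` would exceed 1000, are rejected as
    out-of-range.
    """
    n1, n2 = ratios.n1, ratios.n2
    m = float(np.mean(ratios.values))
    if not np.isfinite(m) or m <= 1.0:
        raise ParameterError(
            f"sample mean {m} is at or below the theoretical infimum 1"
        )

    def gap(d: float) -> float:
        law = GrideLaw(d=d, n1=n1, n2=n2)
        return law.mean() - m

    lo = 1.0 / n1 * (1.0 + 1e-9) + 1e-12  # just above the divergence point
    while gap(lo) < 0:  # mean(lo) finite but already below m: shrink toward 1/n1
        lo = 1.0 / n1 + (lo - 1.0 / n1) / 10.0
        if lo - 1.0 / n1 < 1e-15:
            raise NumericError("mean inversion failed near the divergence boundary")
    if gap(_D_MAX) > 0:
        raise ParameterError(
            f"sample mean {m} too close to 1: implied dimension exceeds {_D_MAX}"
        )
    d_hat = float(optimize.brentq(gap, lo, _D_MAX, xtol=1e-12, rtol=1e-14))
    return IdEstimate(
        method="moments", d_hat=d_hat, n_effective=ratios.n, n1=n1, n2=n2, scale=scale,
    )
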