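"""Synthetic configurations with known intrinsic dimension.

Each generator returns an ``(n, D)`` array and records its ground truth in
a :class:`SyntheticSpec`.  The generators cover the standard benchmark
families for scale-dependent intrinsic-dimension studies:

* a noisy planar **spiral** lifted to 3-D (true id 1, but short-scale noise
  makes it look 3-dimensional);
* **Gaussian clouds** embedded in higher dimension with isotropic Gaussian
  noise added to all coordinates;
* uniform **hypercubes**;
* the **Swiss roll** (2-D strip rolled into 3-D);
* **homogeneous radial** configurations built shell-by-shell around a
  pivot, the exact data-generating process assumed by the ratio
  distributions (exponential shell volumes, uniform directions).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from .errors import ParameterError

__all__ = [
    "SyntheticSpec",
    "make_spiral",
    "make_gaussian_cloud",
    "make_hypercube",
    "make_swissroll",
    "make_homogeneous_radial",
    "unit_ball_volume",
    "simulate",
    "GENERATORS",
]


@dataclass
class SyntheticSpec:
    """Echo of a generator call: name, size, parameters, seed, true id."""

    generator: str
    n: int
    true_id: int
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def unit_ball_volume(d: int) -> float:
    """Volume ``pi^(d/2) / Gamma(d/2 + 1)`` of the d-dimensional unit ball."""
    return float(np.pi ** (d / 2.0) / special.gamma(d / 2.0 + 1.0))


def _check_n(n: int) -> None:
    if n < 3:
        raise ParameterError(f"need n >= 3 observations, got {n}")


def make_spiral(
    n: int = 5000,
    s_bar: float = 1.0,
    sigma_x: float = 0.5,
    sigma_y: float = 0.5,
    sigma_z: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, SyntheticSpec]:
    """Noisy 3-D spiral with a single degree of freedom (true id 1).

    ``u0`` runs over an evenly spaced grid on ``[1/(4 pi), s_bar]``
    (endpoints included), ``u = 2 pi sqrt(u0)``, and the clean coordinates
    are ``x = u cos(u + 2 pi)``, ``y = u sin(u + 2 pi)``, ``z = x^2 + y^2``
    (so ``z = u^2`` exactly without noise).  Independent Gaussian noise
    with standard deviations ``sigma_x, sigma_y, sigma_z`` is then added
    per coordinate.
    """
    _check_n(n)
    lo = 1.0 / (4.0 * np.pi)
    if s_bar <= lo:
        raise ParameterError(f"s_bar must exceed 1/(4*pi) ~= {lo:.4f}, got {s_bar}")
    if min(sigma_x, sigma_y, sigma_z) < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    u0 = np.linspace(lo, s_bar, n)
    u = 2.0 * np.pi * np.sqrt(u0)
    x = u * np.cos(u + 2.0 * np.pi)
    y = u * np.sin(u + 2.0 * np.pi)
    z = x * x + y * y
    pts = np.column_stack([x, y, z])
    pts += rng.normal(0.0, [sigma_x, sigma_y, sigma_z], size=(n, 3))
    spec = SyntheticSpec(
        generator="spiral", n=n, true_id=1, seed=seed,
        params={"s_bar": s_bar, "sigma_x": sigma_x, "sigma_y": sigma_y, "sigma_z": sigma_z},
    )
    return pts, spec


def make_gaussian_cloud(
    n: int = 1000,
    d: int = 2,
    D: int | None = None,
    sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, SyntheticSpec]:
    """Standard d-variate Gaussian embedded in ``D`` dimensions plus noise.

    The signal occupies the first ``d`` coordinates; the remaining
    ``D - d`` are zero before i.i.d. ``N(0, sigma^2)`` noise is added to
    every coordinate.  ``D`` defaults to ``d + 5``.
    """
    _check_n(n)
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    if D is None:
        D = d + 5
    if D < d:
        raise ParameterError(f"embedding dimension D={D} smaller than d={d}")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pts = np.zeros((n, D))
    pts[:, :d] = rng.standard_normal((n, d))
    if sigma > 0:
        pts += rng.normal(0.0, sigma, size=(n, D))
    spec = SyntheticSpec(
        generator="gaussian", n=n, true_id=d, seed=seed,
        params={"d": d, "D": D, "sigma": sigma},
    )
    return pts, spec


def make_hypercube(
    n: int = 10000, d: int = 2, seed: int | None = None
) -> tuple[np.ndarray, SyntheticSpec]:
    """``n`` i.i.d. uniform points in the unit hypercube ``[0, 1]^d``."""
    _check_n(n)
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, d))
    spec = SyntheticSpec(generator="hypercube", n=n, true_id=d, seed=seed, params={"d": d})
    return pts, spec


def make_swissroll(
    n: int = 5000, noise: float = 0.0, seed: int | None = None
) -> tuple[np.ndarray, SyntheticSpec]:
    """Swiss roll: a 2-D strip rolled into 3-D (true id 2).

    Uses the common parametrization ``(t cos t, h, t sin t)`` with
    ``t = 3 pi / 2 * (1 + 2 u)``, ``u, h`` uniform (as implemented in
    scikit-learn); optional isotropic Gaussian perturbation of standard
    deviation ``noise``.
    """
    _check_n(n)
    if noise < 0:
        raise ParameterError("noise must be >= 0")
    from sklearn.datasets import make_swiss_roll

    rng = np.random.default_rng(seed)
    pts, _ = make_swiss_roll(
        n_samples=n, noise=noise, random_state=np.random.RandomState(rng.integers(2**31))
    )
    spec = SyntheticSpec(
        generator="swissroll", n=n, true_id=2, seed=seed, params={"noise": noise}
    )
    return pts, spec


def make_homogeneous_radial(
    n: int = 30000, d: int = 2, rho: float = 1.0, seed: int | None = None
) -> tuple[np.ndarray, SyntheticSpec]:
    """Homogeneous Poisson configuration built radially around a pivot.

    Hyperspherical shell volumes ``v_l`` are drawn i.i.d.
    ``Exponential(rho)``; the ``l``-th radius is
    ``r_l = (sum_{j<=l} v_j / omega_d)^(1/d)`` with ``omega_d`` the unit
    ball volume, so ``omega_d r_l^d`` is ``Erlang(l, rho)`` exactly as the
    model assumes.  Directions are uniform on the unit sphere (uniform
    angle for ``d = 2``, normalized Gaussians for ``d > 2``, random sign
    for ``d = 1``).  The pivot sits at the origin and is *not* included in
    the returned matrix.
    """
    _check_n(n)
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    if rho <= 0:
        raise ParameterError(f"rho must be > 0, got {rho}")
    rng = np.random.default_rng(seed)
    volumes = rng.exponential(1.0 / rho, size=n)
    radii = (np.cumsum(volumes) / unit_ball_volume(d)) ** (1.0 / d)
    if d == 1:
        dirs = rng.choice([-1.0, 1.0], size=(n, 1))
    elif d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        g = rng.standard_normal((n, d))
        dirs = g / np.linalg.norm(g, axis=1, keepdims=True)
    pts = radii[:, None] * dirs
    spec = SyntheticSpec(
        generator="radial", n=n, true_id=d, seed=seed, params={"d": d, "rho": rho}
    )
    return pts, spec


GENERATORS = {
    "spiral": make_spiral,
    "gaussian": make_gaussian_cloud,
    "hypercube": make_hypercube,
    "swissroll": make_swissroll,
    "radial": make_homogeneous_radial,
}


def simulate(generator: str, out_csv, seed: int | None = None, **params):
    """Run a generator and write a CSV plus a JSON sidecar with its spec.

    The sidecar (``<out_csv>.json``) records the generator name, sample
    size, parameters, seed, and the true intrinsic dimension.
    """
    if generator not in GENERATORS:
        raise ParameterError(
            f"unknown generator {generator!r}; choose from {sorted(GENERATORS)}"
        )
    pts, spec = GENERATORS[generator](seed=seed, **params)
    out_csv = Path(out_csv)
    np.savetxt(out_csv, pts, delimiter=",", fmt="%.17g")
    sidecar = out_csv.with_suffix(out_csv.suffix + ".json")
    sidecar.write_text(spec.to_json(indent=2) + "\n")
    return pts, spec
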