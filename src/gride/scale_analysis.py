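"""Scale-dependent intrinsic-dimension profiles.

Two complementary ways of watching the estimated dimension as the
neighborhood grows:

* a **Gride order sweep** — re-estimate on the *full* dataset with
  increasing neighbor orders (``n2 = 2 n1`` by default, doubling ``n1``
  geometrically), so no data are discarded;
* **TWO-NN decimation** — subsample a fraction ``c`` of the points, which
  stretches the second-neighbor distances, and average over replicas.

Both produce a :class:`ScaleProfile` whose x-coordinate is the mean
distance to the outermost neighbor order used, which makes the two
protocols directly comparable on the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, InsufficientDataError, ParameterError
from .estimators import IdEstimate, gride_mle, twonn_mle
from .neighbors import (
    build_neighbor_table,
    generalized_ratios,
    mean_scale,
    validate_matrix,
)

__all__ = [
    "ProfilePoint",
    "ScaleProfile",
    "default_gride_schedule",
    "gride_scan",
    "twonn_decimation_scan",
    "profile_to_table",
    "table_to_profile",
    "write_profile",
    "read_profile",
]

_COLUMNS = ["n1", "n2", "c", "scale", "d_hat", "ci_low", "ci_high", "replicas", "seed"]


@dataclass
class ProfilePoint:
    """One schedule point: neighbor orders (or fraction), scale, estimate."""

    estimate: IdEstimate
    n1: int | None = None
    n2: int | None = None
    fraction: float | None = None
    scale: float | None = None
    replicas: int = 1


@dataclass
class ScaleProfile:
    """Ordered sequence of estimates across a neighborhood schedule."""

    points: list[ProfilePoint] = field(default_factory=list)
    kind: str = "gride"  # or "decimation"

    def __len__(self) -> int:
        return len(self.points)

    def scales(self) -> np.ndarray:
        return np.array([p.scale for p in self.points], dtype=float)

    def estimates(self) -> np.ndarray:
        return np.array([p.estimate.d_hat for p in self.points], dtype=float)


def default_gride_schedule(n: int, ratio: int = 2, n1_max: int = 256) -> list[int]:
    """Double ``n1`` geometrically from 1 while ``n1 * ratio <= n - 1``."""
    schedule, n1 = [], 1
    while n1 * ratio <= n - 1 and n1 <= n1_max:
        schedule.append(n1)
        n1 *= 2
    if not schedule:
        raise InsufficientDataError(f"dataset of size {n} too small for any sweep")
    return schedule


def gride_scan(
    data,
    n1_schedule: list[int] | None = None,
    ratio: int = 2,
    level: float = 0.95,
    seed: int | None = None,
    bootstrap_reps: int = 0,
    metric: str = "euclidean",
) -> ScaleProfile:
    """Gride estimates across neighbor orders on the full dataset.

    No subsampling is performed at any point of the sweep: larger scales
    are reached purely by raising the neighbor orders ``(n1, ratio*n1)``.
    """
    x = validate_matrix(data)
    n = x.shape[0]
    if ratio < 2:
        raise ParameterError(f"order multiplier must be >= 2, got {ratio}")
    if n1_schedule is None:
        n1_schedule = default_gride_schedule(n, ratio)
    n1_schedule = sorted(int(v) for v in n1_schedule)
    if n1_schedule[0] < 1:
        raise ParameterError("n1 schedule entries must be >= 1")
    kmax = n1_schedule[-1] * ratio
    if kmax > n - 1:
        raise CapacityError(
            f"largest order n2 = {kmax} exceeds the n - 1 = {n - 1} available neighbors"
        )
    table = build_neighbor_table(x, kmax=kmax, metric=metric)
    profile = ScaleProfile(kind="gride")
    for j, n1 in enumerate(n1_schedule):
        n2 = n1 * ratio
        sc = mean_scale(table, n2)
        est = gride_mle(
            generalized_ratios(table, n1, n2),
            level=level,
            bootstrap_reps=bootstrap_reps,
            seed=None if seed is None else seed + j,
            scale=sc,
        )
        profile.points.append(ProfilePoint(estimate=est, n1=n1, n2=n2, scale=sc))
    return profile


def twonn_decimation_scan(
    data,
    fractions,
    replicas: int = 1,
    seed: int | None = None,
    level: float = 0.95,
    metric: str = "euclidean",
) -> ScaleProfile:
    """Decimated TWO-NN: subsample fractions ``c``, average over replicas.

    For each ``c`` the scan draws ``replicas`` independent subsamples
    without replacement of size ``round(c * n)``, applies the TWO-NN MLE
    within each, and reports the replica mean together with the mean
    second-neighbor distance.  With more than one replica the interval is
    a ±2-standard-error band across replicas; with a single replica the
    analytic confidence interval of the MLE is passed through.
    """
    x = validate_matrix(data)
    n = x.shape[0]
    if replicas < 1:
        raise ParameterError(f"replicas must be >= 1, got {replicas}")
    fractions = sorted((float(c) for c in fractions), reverse=True)
    rng = np.random.default_rng(seed)
    profile = ScaleProfile(kind="decimation")
    for c in fractions:
        if not (0.0 < c <= 1.0):
            raise ParameterError(f"fractions must lie in (0, 1], got {c}")
        m = int(round(c * n))
        if m < 3:
            raise InsufficientDataError(
                f"fraction c={c} keeps {m} points; at least 3 are required"
            )
        d_hats, scales = [], []
        one_rep_est = None
        for _ in range(replicas):
            sub = x if m == n else x[rng.choice(n, size=m, replace=False)]
            table = build_neighbor_table(sub, kmax=2, metric=metric)
            sc = mean_scale(table, 2)
            est = twonn_mle(generalized_ratios(table, 1, 2), level=level, scale=sc)
            d_hats.append(est.d_hat)
            scales.append(sc)
            one_rep_est = est
        mean_d = float(np.mean(d_hats))
        mean_sc = float(np.mean(scales))
        if replicas > 1:
            se = float(np.std(d_hats, ddof=1)) / np.sqrt(replicas)
            est = IdEstimate(
                method="twonn_mle", d_hat=mean_d,
                ci_low=max(mean_d - 2.0 * se, 1e-12), ci_high=mean_d + 2.0 * se,
                level=level, n_effective=m, n1=1, n2=2, scale=mean_sc, seed=seed,
            )
        else:
            est = one_rep_est
        profile.points.append(
            ProfilePoint(estimate=est, n1=1, n2=2, fraction=c, scale=mean_sc,
                         replicas=replicas)
        )
    return profile


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def profile_to_table(profile: ScaleProfile) -> pd.DataFrame:
    """Lossless tabular form, one row per schedule point."""
    rows = []
    for p in profile.points:
        e = p.estimate
        rows.append({
            "n1": p.n1, "n2": p.n2, "c": p.fraction, "scale": p.scale,
            "d_hat": e.d_hat, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "replicas": p.replicas, "seed": e.seed,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def table_to_profile(df: pd.DataFrame, kind: str = "gride") -> ScaleProfile:
    """Inverse of :func:`profile_to_table` (method tag inferred from kind)."""
    profile = ScaleProfile(kind=kind)
    method = "gride_mle" if kind == "gride" else "twonn_mle"
    for _, row in df.iterrows():
        est = IdEstimate(
            method=method,
            d_hat=float(row["d_hat"]),
            ci_low=_opt_float(row["ci_low"]),
            ci_high=_opt_float(row["ci_high"]),
            n1=_opt_int(row["n1"]), n2=_opt_int(row["n2"]),
            scale=_opt_float(row["scale"]),
            seed=_opt_int(row["seed"]),
        )
        profile.points.append(
            ProfilePoint(
                estimate=est, n1=_opt_int(row["n1"]), n2=_opt_int(row["n2"]),
                fraction=_opt_float(row["c"]), scale=_opt_float(row["scale"]),
                replicas=int(row["replicas"]) if not pd.isna(row["replicas"]) else 1,
            )
        )
    return profile


def write_profile(profile: ScaleProfile, path) -> None:
    profile_to_table(profile).to_csv(path, sep="\t", index=False)


def read_profile(path, kind: str = "gride") -> ScaleProfile:
    df = pd.read_csv(path, sep="\t")
    return table_to_profile(df, kind=kind)


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def _opt_int(v):
    return None if pd.isna(v) else int(v)
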