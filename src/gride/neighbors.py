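"""Exact nearest-neighbor tables and distance-ratio extraction.

Ratios of neighbor distances are sensitive to order swaps at small
distances, so neighbor search is always exact (scikit-learn brute force or
tree backends, never approximate).  Ties between equidistant neighbors are
broken by original row index — a convention, stated here because the
statistics do not depend on it for continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import (
    CapacityError,
    DataError,
    DuplicatePointsError,
    ParameterError,
)

__all__ = [
    "NeighborTable",
    "RatioSample",
    "ConsecutiveRatios",
    "validate_matrix",
    "build_neighbor_table",
    "generalized_ratios",
    "consecutive_ratios",
    "mean_scale",
    "read_matrix",
    "read_distance_table",
]


@dataclass
class NeighborTable:
    """Per-observation sorted distances to the first ``kmax`` neighbors.

    ``distances[i, l-1]`` is the distance from observation ``i`` to its
    ``l``-th nearest distinct neighbor (1-based order, self excluded).
    ``indices`` may be ``None`` when the table was ingested from a
    precomputed distance file.
    """

    distances: np.ndarray
    indices: np.ndarray | None
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.distances.shape[0]

    @property
    def kmax(self) -> int:
        return self.distances.shape[1]

    def _check_order(self, order: int) -> None:
        if order < 1 or order > self.kmax:
            raise CapacityError(
                f"neighbor order {order} outside the stored range 1..{self.kmax}; "
                "rebuild the table with a larger kmax"
            )


@dataclass
class RatioSample:
    """Generalized ratios ``r_{i,n2} / r_{i,n1}`` for one order pair."""

    values: np.ndarray
    n1: int
    n2: int

    @property
    def n(self) -> int:
        return self.values.size

    def log(self) -> np.ndarray:
        return np.log(self.values)


@dataclass
class ConsecutiveRatios:
    """Matrix of consecutive ratios ``r_{i,l}/r_{i,l-1}``, ``l = 2..L``."""

    values: np.ndarray  # shape (n, L-1); column j holds order l = j + 2
    L: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def weighted_log_sum(self) -> float:
        """``sum_i sum_{l=2..L} (l-1) * log mu_{i,l}``, the MG sufficient statistic."""
        weights = np.arange(1, self.L)  # l - 1 for l = 2..L
        return float((np.log(self.values) * weights).sum())


def validate_matrix(data) -> np.ndarray:
    """Coerce to an ``(n, D)`` float array; n >= 3, all entries finite."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise DataError(f"expected a 2-D data matrix, got {x.ndim}-D")
    if x.shape[0] < 3:
        raise DataError(f"need at least 3 observations, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))[0]
        raise DataError(f"non-finite value at row {bad[0]}, column {bad[1]}")
    return x


def build_neighbor_table(
    data,
    kmax: int,
    metric: str = "euclidean",
    duplicates: str = "error",
) -> NeighborTable:
    """Exact neighbor search, sorted by (distance, row index).

    Parameters
    ----------
    data : array-like, shape (n, D)
        Observations in rows.
    kmax : int
        Highest neighbor order to store; ``kmax <= n - 1``.
    metric : str
        Any scikit-learn exact metric; Euclidean by default.
    duplicates : {"error", "drop"}
        Duplicate rows make first-neighbor distances zero and ratios
        infinite.  ``"error"`` (default) raises naming the offending rows;
        ``"drop"`` keeps the first occurrence of each duplicate group.
    """
    x = validate_matrix(data)
    if duplicates not in ("error", "drop"):
        raise ParameterError(f"unknown duplicate policy {duplicates!r}")
    if duplicates == "drop":
        _, keep = np.unique(x, axis=0, return_index=True)
        x = x[np.sort(keep)]
        if x.shape[0] < 3:
            raise DataError("fewer than 3 distinct observations after dropping duplicates")
    n = x.shape[0]
    if not (1 <= kmax <= n - 1):
        raise CapacityError(f"kmax must be in 1..{n - 1}, got {kmax}")

    # brute force when the requested order is a sizable fraction of n (tree
    # traversal degenerates there) and the distance matrix fits comfortably
    algorithm = "brute" if (kmax > n // 10 or n <= 2000) else "auto"
    nn = NearestNeighbors(n_neighbors=kmax + 1, metric=metric, algorithm=algorithm)
    nn.fit(x)
    dist, idx = nn.kneighbors(x)

    # remove the query point itself from each row (it may not be listed
    # first when duplicates are present); if absent, drop the last entry
    rows = np.arange(n)
    self_mask = idx == rows[:, None]
    has_self = self_mask.any(axis=1)
    drop_col = np.where(has_self, self_mask.argmax(axis=1), kmax)
    keep = np.ones_like(idx, dtype=bool)
    keep[rows, drop_col] = False
    dist = dist[keep].reshape(n, kmax)
    idx = idx[keep].reshape(n, kmax)

    # deterministic tie-break: stable order by (distance, neighbor index)
    order = np.lexsort((idx, dist), axis=1)
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)

    zero_rows = np.flatnonzero(dist[:, 0] <= 0)
    if zero_rows.size:
        raise DuplicatePointsError(zero_rows.tolist())
    return NeighborTable(distances=dist, indices=idx, metric=metric)


def generalized_ratios(
    table: NeighborTable, n1: int, n2: int, subset=None
) -> RatioSample:
    """Ratios ``r_{i,n2} / r_{i,n1}`` for every observation.

    ``subset`` (row indices) restricts the ratios to a subset of center
    points while keeping neighbor distances computed on the full
    configuration — used e.g. to estimate on the core of a pivot-centered
    configuration without boundary truncation of the neighborhoods.
    """
    if not (1 <= n1 < n2):
        raise ParameterError(f"need 1 <= n1 < n2, got ({n1}, {n2})")
    table._check_order(n2)
    values = table.distances[:, n2 - 1] / table.distances[:, n1 - 1]
    if subset is not None:
        values = values[subset]
    return RatioSample(values=values, n1=n1, n2=n2)


def consecutive_ratios(table: NeighborTable, L: int) -> ConsecutiveRatios:
    """Consecutive ratios ``r_{i,l}/r_{i,l-1}`` for ``l = 2..L``.

    Their row-wise product telescopes to ``r_{i,L}/r_{i,1}`` and, weighted
    by ``l-1`` in the log, they carry the full MG likelihood.
    """
    if L < 2:
        raise ParameterError(f"L must be >= 2, got {L}")
    table._check_order(L)
    r = table.distances[:, :L]
    return ConsecutiveRatios(values=r[:, 1:] / r[:, :-1], L=L)


def mean_scale(table: NeighborTable, order: int) -> float:
    """Mean distance to the ``order``-th neighbor; the x-axis of scale profiles."""
    table._check_order(order)
    return float(table.distances[:, order - 1].mean())


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------


def read_matrix(path, delimiter: str | None = None) -> np.ndarray:
    """Read a delimited numeric matrix (rows = observations, header optional).

    The delimiter is sniffed (comma/tab/whitespace) when not given; a
    non-numeric first row is treated as a header.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surfaced as a data error
        raise DataError(f"cannot read {path}: {exc}") from exc
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        x = df.astype(float).to_numpy()
    except (TypeError, ValueError):
        bad = _first_non_numeric(df)
        raise DataError(
            f"non-numeric cell at row {bad[0]}, column {bad[1]} of {path}"
        ) from None
    return validate_matrix(x)


def read_distance_table(path, metric: str = "euclidean") -> NeighborTable:
    """Ingest precomputed neighbor distances (TSV: row index, then distances).

    Each row holds an observation index followed by its sorted neighbor
    distances; neighbor identities are unavailable in this layout.
    """
    raw = read_matrix(path, delimiter=None)
    if raw.shape[1] < 3:
        raise DataError("distance table needs an index column plus >= 2 distances")
    order = np.argsort(raw[:, 0], kind="stable")
    dist = raw[order, 1:]
    if np.any(np.diff(dist, axis=1) < 0):
        raise DataError("distance rows must be nondecreasing in neighbor order")
    if np.any(dist[:, 0] <= 0):
        raise DuplicatePointsError(np.flatnonzero(dist[:, 0] <= 0).tolist())
    return NeighborTable(distances=dist, indices=None, metric=metric)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_non_numeric(df: pd.DataFrame) -> tuple[int, int]:
    for i, row in enumerate(df.itertuples(index=False)):
        for j, v in enumerate(row):
            if not _is_number(v):
                return i, j
    return -1, -1
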