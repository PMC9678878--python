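"""Exception hierarchy.

``ParameterError`` covers invalid estimator/distribution parameters,
``DataError`` covers problems with the observed data (duplicates,
degenerate ratios, requests beyond the stored neighbor order), and
``NumericError`` covers optimizer/quadrature failures.
"""


class GrideError(Exception):
    """Base class for all package errors."""


class ParameterError(GrideError, ValueError):
    """Invalid distribution or estimator parameters."""


class DataError(GrideError, ValueError):
    """The input data violate a precondition of the requested operation."""


class DuplicatePointsError(DataError):
    """Zero first-neighbor distances: distance ratios would be infinite."""

    def __init__(self, rows, message=None):
        self.rows = list(rows)
        if message is None:
            message = (
                f"duplicate points detected (zero first-neighbor distance) at rows "
                f"{self.rows[:20]}{'...' if len(self.rows) > 20 else ''}; "
                "drop duplicates before estimation (policy='drop') or clean the data"
            )
        super().__init__(message)


class DegenerateRatiosError(DataError):
    """All ratios equal one: the likelihood has no maximizer."""


class BoundaryRatioError(DataError):
    """A generalized ratio equals one where the likelihood requires > 1."""


class CapacityError(DataError):
    """A neighbor order beyond the stored ``kmax`` was requested."""


class InsufficientDataError(DataError):
    """Too few observations survive filtering for the estimator to run."""


class NumericError(GrideError, RuntimeError):
    """Numerical failure (bracket exhaustion, divergent quadrature, ...)."""
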