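"""Structured exceptions raised across the package."""


class IsingSelectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IsingSelectError, ValueError):
    """An input object violates a structural invariant (shape, symmetry, domain)."""


class DimensionMismatchError(ValidationError):
    """Two objects that must share a dimension do not."""


class NonBinaryError(ValidationError):
    """A data entry is neither 0 nor 1."""


class EnumerationCapError(IsingSelectError):
    """The requested exact enumeration exceeds the configured node cap."""


class EmptySupportError(IsingSelectError, ValueError):
    """The truncated support contains no response pattern (k > m)."""


class RowBelowCutoffError(ValidationError):
    """A data row has sum score below the cutoff it was supposedly selected on."""


class DegenerateNodeError(IsingSelectError):
    """A nodewise regression response is single-valued, so no logistic fit exists."""

    def __init__(self, nodes, message=None):
        self.nodes = list(nodes) if not isinstance(nodes, int) else [nodes]
        super().__init__(
            message or f"degenerate node(s) {self.nodes}: response has a single class"
        )


class SingularInformationError(IsingSelectError):
    """The observed information matrix is singular; some parameters are unidentified."""


class ImpossibleConditionError(IsingSelectError, ValueError):
    """A conditioning event has probability zero (predictor sum below k - 1)."""


class CalibrationError(IsingSelectError):
    """Fixture calibration failed within the allowed number of redraws."""
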