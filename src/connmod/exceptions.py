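"""Exception hierarchy for pipeline stage errors."""


class ConnmodError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ConnmodError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(ConnmodError, ValueError):
    """A configuration object is internally inconsistent."""


class DegenerateSeriesError(ConnmodError):
    """A time-series column has zero variance; correlation is undefined."""


class DegenerateCovarianceError(ConnmodError):
    """A constructed covariance could not be repaired to positive semidefinite."""


class SingularFitError(ConnmodError):
    """The distance-trend regression design is singular (all distances equal)."""


class ShapeError(ConnmodError, ValueError):
    """Matrix dimensions do not match between pipeline stages."""


class DisconnectedGraphError(ConnmodError):
    """An operation requiring a connected graph received a disconnected one."""


class DegenerateGraphError(ConnmodError):
    """A graph without usable weights (e.g. all zero) was supplied."""


class DegenerateReferenceError(ConnmodError):
    """Random-reference normalisation is undefined (zero reference clustering)."""


class UndefinedPIError(ConnmodError):
    """Participation is undefined for a node with zero total strength."""


class InsufficientDataError(ConnmodError):
    """Too few subjects (or observations) for the requested statistic."""


class CompletenessError(ConnmodError):
    """A subject is missing a metric required by the feature matrix."""
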