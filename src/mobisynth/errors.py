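"""Exception hierarchy for the synthesis pipeline.

Every stage raises a subclass of :class:`MobisynthError`, so the CLI can map
any pipeline failure to a non-zero exit with a single diagnostic line.
"""


class MobisynthError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MobisynthError):
    """An infeasible or inconsistent configuration value; names the field."""


class DataError(MobisynthError):
    """Malformed or missing input data (e.g. a zone without a centroid)."""


class ValidationError(MobisynthError):
    """A serialized table violates its schema; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConvergenceError(MobisynthError):
    """Iterative fitting failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class FeasibilityError(MobisynthError):
    """A sampling or assignment step has no feasible outcome."""


class FitError(MobisynthError):
    """A model fit (e.g. gravity deterrence) could not be completed."""
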