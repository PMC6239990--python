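"""Exception hierarchy used across the toolkit."""


class VolsurfError(Exception):
    """Base class for all toolkit errors."""


class FormatError(VolsurfError, ValueError):
    """A file or in-memory payload violates the expected format."""


class ValidationError(VolsurfError, ValueError):
    """An argument or configuration value violates a precondition."""


class OutOfHullError(VolsurfError):
    """A point fell outside the grid hull of a dense field or volume."""


class FieldInversionError(VolsurfError):
    """Fixed-point inversion of a displacement field did not converge.

    Carries the residual (mm) achieved at the last iteration.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class DegenerateMetricError(VolsurfError):
    """A metric is undefined for the given inputs (e.g. empty label support)."""
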