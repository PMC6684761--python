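"""Exception hierarchy.

All package errors derive from :class:`CoactError`. Argument-validation
errors additionally derive from :class:`ValueError` so that callers doing
generic input validation catch them without importing this module.
"""

from __future__ import annotations


class CoactError(Exception):
    """Base class for all errors raised by coact."""


class InvalidArgumentError(CoactError, ValueError):
    """A function argument violates a documented precondition."""


class SchemaError(CoactError):
    """A file or config does not match its documented schema."""


class DataError(CoactError):
    """A file matches the schema but its contents are inconsistent."""


class ConfigurationError(CoactError):
    """A configuration value is unusable (e.g. a zero cost normalizer)."""


class CalibrationError(CoactError):
    """Parameter calibration failed (violated existence inequality)."""


class InfeasibleError(CoactError):
    """The torque demand cannot be met within actuator bounds.

    Attributes
    ----------
    gap : float or None
        Smallest achievable infinity-norm torque residual (N.m).
    samples : list[int] or None
        Sample indices that failed, for trajectory-level solves.
    """

    def __init__(self, message: str, gap: float | None = None,
                 samples: list[int] | None = None):
        super().__init__(message)
        self.gap = gap
        self.samples = samples
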