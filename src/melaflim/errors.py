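"""Exception hierarchy shared across the package.

Validation errors signal bad inputs or metadata (CLI exit code 2);
capability errors signal requests the data cannot support, such as
bi-exponential fitting of 4-time-channel stacks (CLI exit code 3).
"""


class MelaflimError(Exception):
    """Base class for all package errors."""


class ValidationError(MelaflimError, ValueError):
    """Invalid input data, metadata or configuration."""


class ShapeError(ValidationError):
    """Array geometry disagrees with metadata or between inputs."""


class CapabilityError(MelaflimError):
    """The requested analysis is not supported on this data.

    The canonical case: per-pixel bi-exponential fitting or phasor
    transformation of a 4-time-channel clinical stack, where the slope
    (Pseudo-FLIM) method is the designated analysis.
    """


class UndefinedPhasorError(ValidationError):
    """Phasor requested for a decay with zero total counts."""
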