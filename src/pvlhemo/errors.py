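"""Exception hierarchy.

Validation and usage problems (bad inputs, broken meshes, missing channels)
derive from :class:`ValidationError`; the CLI maps these to exit code 2.
Everything else is an internal error (exit code 1).
"""


class PVLHemoError(Exception):
    """Base class for all package errors."""


class ValidationError(PVLHemoError, ValueError):
    """Invalid input data or parameters."""


class DomainError(ValidationError):
    """Argument outside the mathematical domain of an operation."""


class GeometryError(ValidationError):
    """Inconsistent or unconstructible geometry."""


class SchemaError(ValidationError):
    """A required data channel is missing or malformed."""


class UnitError(ValidationError):
    """Declared units do not match what an operation expects."""


class UsageError(ValidationError):
    """An operation was called in a way that cannot be satisfied."""


class CorrespondenceError(ValidationError):
    """Keyframe meshes do not share node correspondence."""


class ConvergenceError(PVLHemoError, RuntimeError):
    """An iterative solve failed to reach its tolerance."""
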