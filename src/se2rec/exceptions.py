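"""Exception hierarchy used across the package.

All errors raised by se2rec derive from :class:`Se2RecError`, so callers
(and the CLI) can distinguish package failures from programming errors.
"""


class Se2RecError(Exception):
    """Base class for all se2rec errors."""


class ConfigurationError(Se2RecError, ValueError):
    """A parameter set is invalid (names the offending field)."""


class DimensionError(Se2RecError, ValueError):
    """Array shapes are inconsistent with each other or with parameters."""


class DomainError(Se2RecError, ValueError):
    """An argument lies outside the mathematically admissible domain."""


class ResourceError(Se2RecError, RuntimeError):
    """A guard against accidentally large dense computations fired."""


class NumericalDegeneracyError(Se2RecError, ArithmeticError):
    """A quantity that must be strictly positive numerically vanished."""


class PreconditionError(Se2RecError, ValueError):
    """A documented precondition of an operation was violated."""


class StorageError(Se2RecError, OSError):
    """A file could not be read or written (names the path)."""
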