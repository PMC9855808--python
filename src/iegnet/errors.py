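"""Exception hierarchy used across the package."""


class IegnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IegnetError, ValueError):
    """Raised when an input table, spec or argument fails validation."""


class UndefinedAreaError(IegnetError, ValueError):
    """Raised when a region has zero grid points, so its area (and hence
    density) is undefined rather than zero or infinite."""


class NumericalError(IegnetError, RuntimeError):
    """Raised when an iterative numerical routine fails to converge or a
    quantity (e.g. small-world sigma against degenerate nulls) is undefined."""
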