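"""Exception hierarchy shared across the package.

Exit-code convention for the CLI: 0 success, 2 parameter error,
3 I/O error.
"""


class FoascopeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(FoascopeError):
    """An argument violates a documented precondition."""

    exit_code = 2


class PlacementError(FoascopeError):
    """Rejection sampling could not place the requested number of cells."""

    exit_code = 2


class ImageIOError(FoascopeError):
    """A file could not be read or written."""

    exit_code = 3


class EvanescentRegimeError(ParameterError):
    """Total internal reflection does not hold; penetration depth undefined."""


class UndefinedRateError(ParameterError):
    """An identification rate was requested with zero ground-truth cells."""
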