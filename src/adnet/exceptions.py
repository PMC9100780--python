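"""Exception hierarchy.

All errors raised by the package derive from :class:`AdnetError` so callers can
catch package failures with a single clause while still distinguishing bad user
input from bad internal state.
"""


class AdnetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AdnetError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(AdnetError, ValueError):
    """A network or training configuration is internally inconsistent."""


class StateError(AdnetError, RuntimeError):
    """An operation was called in a state where it is undefined (e.g. empty store)."""


class FormatError(AdnetError, ValueError):
    """A file does not conform to its declared on-disk format."""


class DegenerateDimensionError(AdnetError, ValueError):
    """Too few samples for the requested dimensionality of a multivariate test."""
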