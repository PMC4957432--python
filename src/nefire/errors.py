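"""Exception hierarchy shared across the package."""


class NefireError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NefireError, ValueError):
    """An argument violates an operation's precondition (non-finite angle,
    non-positive elapsed time, negative count, ...)."""


class ConfigurationError(NefireError, ValueError):
    """A scenario or simulation configuration is internally inconsistent
    (queue overruns its arc, refractory equation has no crossing, ...)."""


class NumericalError(NefireError, RuntimeError):
    """An iterative numerical routine failed to converge."""


class InconclusiveResultError(NefireError, RuntimeError):
    """An analysis cannot produce a trustworthy number from the given data
    (no plateau in a saturation sweep, too few events for a period, ...).
    Raised instead of fabricating a value."""
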