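"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`EmtScreenError`, so callers can distinguish validation problems
from genuine bugs.
"""


class EmtScreenError(Exception):
    """Base class for all errors raised by emtscreen."""


class ConfigError(EmtScreenError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(EmtScreenError, ValueError):
    """An input table violates a structural precondition."""


class DegenerateInputError(EmtScreenError, ValueError):
    """Input is structurally valid but statistically degenerate
    (e.g. a constant covariate, zero-variance correlation target)."""


class InsufficientDataError(EmtScreenError, ValueError):
    """Too few usable observations for the requested computation."""


class ConsistencyError(EmtScreenError, ValueError):
    """Two inputs that must describe the same cohort do not match."""


class ConvergenceError(EmtScreenError, RuntimeError):
    """An iterative fit failed to converge; the message carries diagnostics."""
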