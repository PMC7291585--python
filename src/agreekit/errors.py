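"""Exception hierarchy for agreekit.

``ConfigurationError`` signals a problem with how the user invoked the
library (bad column mapping, malformed settings); ``DataError`` signals a
problem with the data itself; ``ConvergenceError`` signals a model fit that
could not be completed.  The CLI maps usage errors to exit code 2 and
data/convergence errors to exit code 1.
"""


class AgreekitError(Exception):
    """Base class for all agreekit errors."""


class ConfigurationError(AgreekitError):
    """Invalid user configuration (missing column, bad mapping, bad flag)."""


class DataError(AgreekitError):
    """Input data violates a structural precondition."""


class ConvergenceError(AgreekitError):
    """A model fit failed and no usable result is available."""


class UndefinedIndexError(AgreekitError):
    """An agreement index is mathematically undefined for the given fit."""
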