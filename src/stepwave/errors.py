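"""Exception hierarchy.

``DataError`` covers malformed *contents* (exit code 1 at the CLI),
``FormatError`` covers unreadable *structure*, and ``ParameterError``
covers caller mistakes (exit code 2 at the CLI).
"""


class StepwaveError(Exception):
    """Base class for all package errors."""


class FormatError(StepwaveError):
    """File structure cannot be parsed (missing columns, bad tokens)."""


class DataError(StepwaveError):
    """File parsed but contents violate an invariant (non-monotonic time, ...)."""


class ParameterError(StepwaveError, ValueError):
    """Invalid argument or configuration value."""


class NoDominantFrequencyError(StepwaveError):
    """The spectrum has no peak standing out from the in-band floor."""
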