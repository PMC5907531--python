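"""Exception hierarchy.

Validation errors signal malformed inputs (bad files, inconsistent
schemes); numerical errors signal a computation that produced
non-finite or otherwise unusable results at valid inputs.
"""


class HergkinError(Exception):
    """Base class for all package errors."""


class ValidationError(HergkinError):
    """Malformed or inconsistent user input (files, parameters, configs)."""


class ConfigurationError(ValidationError):
    """A scheme/parameter/protocol combination that cannot be assembled."""


class InvalidParameterError(HergkinError):
    """Rate or state evaluation produced a non-finite result."""


class NumericalError(HergkinError):
    """A numerical procedure failed (singular matrix, probability leak, instability)."""


class FitError(HergkinError):
    """Nonlinear fit did not converge or was given a degenerate window."""


class NoAPError(HergkinError):
    """No action potential detected in a voltage trace."""
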