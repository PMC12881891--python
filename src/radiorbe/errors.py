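"""Exception hierarchy.

``InputError`` covers malformed scalar arguments, ``ValidationError`` malformed
tables or configuration, and ``UnattainableEffectError`` iso-effect queries that
no dose on the curve can satisfy. The CLI maps ``ValidationError`` to exit code
2 and ``UnattainableEffectError`` to exit code 3.
"""


class RadiorbeError(Exception):
    """Base class for all package errors."""


class InputError(RadiorbeError, ValueError):
    """A scalar argument violates a precondition (negative dose, PE > 1, ...)."""


class ValidationError(InputError):
    """A table, file or configuration is malformed (missing columns, duplicate
    replicates, missing unirradiated control, ...)."""


class InsufficientDataError(InputError):
    """Too few usable observations for the requested fit."""


class UnattainableEffectError(RadiorbeError):
    """The requested effect level lies outside what the curve can reach."""
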