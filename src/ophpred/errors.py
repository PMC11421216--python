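"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ValidationError` -> 2,
:class:`MissingInputError` -> 3.
"""


class OphPredError(Exception):
    """Base class for all errors raised by ophpred."""


class ValidationError(OphPredError):
    """Input data violates a documented invariant (bad pH, duplicate id, ...)."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the file and, where known, the line."""


class MissingInputError(OphPredError):
    """A referenced input file does not exist."""
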