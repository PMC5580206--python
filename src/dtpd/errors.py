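"""Exception hierarchy shared across the package."""


class DTPDError(Exception):
    """Base class for all package errors."""


class InputError(DTPDError, ValueError):
    """Raised when inputs violate a precondition (empty data, bad ranges)."""


class DegenerateInputError(DTPDError, ValueError):
    """Raised when an input is formally valid but degenerate for the
    requested computation (constant dissimilarities, zero variance, ...)."""


class RecordValidationError(DTPDError, ValueError):
    """Raised when a record or file row fails schema validation; the message
    names the offending row / field / rule."""
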