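"""Exception hierarchy shared across the package."""


class PaleosnakeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PaleosnakeError, ValueError):
    """An input violates a documented precondition (bad value, wrong domain)."""


class ParseError(PaleosnakeError, ValueError):
    """A matrix or tree file could not be interpreted."""


class DegenerateDesignError(ValidationError):
    """A regression design matrix has no usable variation."""
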