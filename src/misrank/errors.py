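"""Exception and warning types shared across the package."""


class MisrankError(Exception):
    """Base class for all misrank errors."""


class ParseError(MisrankError):
    """A line of an input file could not be parsed; the message names the line."""


class ValidationError(MisrankError):
    """Parsed input violates a structural invariant (score bounds, conflicts, ...)."""


class DataQualityWarning(UserWarning):
    """Recoverable input oddity: duplicate entries, empty filtered classes, ..."""
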