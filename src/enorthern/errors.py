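"""Exception hierarchy shared across the package."""


class ENorthernError(Exception):
    """Base class for all package errors."""


class ParseError(ENorthernError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ENorthernError):
    """Input violated a domain invariant (duplicate gene, score range, ...)."""
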