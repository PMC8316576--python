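"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, MissingInputError -> 3.
"""


class DmrkitError(Exception):
    """Base class for all package errors."""


class ValidationError(DmrkitError):
    """Input violates a documented contract (bad values, bad schema)."""


class ParseError(ValidationError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class MissingInputError(DmrkitError):
    """A required input file or upstream stage output is absent."""
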