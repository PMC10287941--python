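"""Exception hierarchy shared by all modules."""


class TriageError(Exception):
    """Base class for all package errors."""


class ValidationError(TriageError, ValueError):
    """Input violates a documented contract (bad coordinates, shapes, values)."""


class ParseError(TriageError, ValueError):
    """A file could not be parsed under the requested dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)
        self.path = path
        self.line = line
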