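"""Exception hierarchy for the membranome pipeline."""


class MembranomeError(Exception):
    """Base class for all package errors."""


class FormatError(MembranomeError):
    """A file does not conform to the expected tabular/FASTA layout."""


class MissingColumnError(FormatError):
    """A declared column is absent from a delimited file."""

    def __init__(self, column: str, path: str) -> None:
        self.column = column
        self.path = path
        super().__init__(f"missing column {column!r} in {path}")


class RowParseError(FormatError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}")


class ValidationError(MembranomeError):
    """A parsed value violates a domain invariant (e.g. negative score)."""


class ConfigError(MembranomeError):
    """An analysis or generator configuration is inconsistent."""
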