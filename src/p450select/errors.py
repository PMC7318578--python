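"""Exception hierarchy.

All package-specific failures derive from :class:`P450SelectError` so callers
can catch one base class. Input-format problems (missing columns, unparsable
cells) and domain-validation problems (non-positive Vmax, duplicate keys) are
kept distinct because the CLI maps them to different exit codes.
"""


class P450SelectError(Exception):
    """Base class for all package errors."""


class DataFormatError(P450SelectError):
    """File-level structural problem: missing column, empty file, bad header."""


class DataParseError(DataFormatError):
    """Cell-level problem; message carries the line number and column."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.line = line
        self.column = column


class DataValidationError(P450SelectError):
    """Values violate a domain invariant (signs, duplicates, missing atoms)."""


class FitError(P450SelectError):
    """A regression cannot be set up (under-determined or singular design)."""
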