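"""Exception hierarchy shared across the package.

Validation errors (bad parameter values, inconsistent inputs) and schema
errors (malformed input tables) are kept distinct so the command-line
layer can map them to different exit codes.
"""


class SpinedynError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpinedynError, ValueError):
    """A parameter or input value violates a documented precondition."""


class SchemaError(SpinedynError, ValueError):
    """An input table does not conform to the documented column schema."""

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        loc = []
        if file is not None:
            loc.append(f"file={file}")
        if row is not None:
            loc.append(f"row={row}")
        if column is not None:
            loc.append(f"column={column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.file = file
        self.row = row
        self.column = column
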