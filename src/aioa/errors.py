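"""Exception hierarchy shared across the package."""


class AioaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AioaError):
    """A file does not match the expected schema (missing columns etc.)."""


class ParseError(AioaError):
    """A cell or record could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class SchemaError(AioaError):
    """A serialized model references unknown features or a bad version."""


class ValidationError(AioaError):
    """An in-memory object violates its invariants."""


class BudgetInfeasibleError(AioaError):
    """No tree under the size threshold could be grown.

    ``smallest_size_bytes`` records the smallest footprint seen, so the
    caller can tell how far off the budget was.
    """

    def __init__(self, message: str, smallest_size_bytes: int | None = None):
        super().__init__(message)
        self.smallest_size_bytes = smallest_size_bytes
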