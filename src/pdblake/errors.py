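"""Exception hierarchy shared by all pdblake modules."""


class PdbLakeError(Exception):
    """Base class for all pdblake errors."""


class CompressionError(PdbLakeError):
    """A gzip stream could not be inflated (corrupt or truncated)."""


class MalformedLineError(PdbLakeError):
    """A PDB record line violates the fixed-width format.

    Carries the 1-based line number and the offending line so strict-mode
    failures can name the exact input position.
    """

    def __init__(self, message: str, line_number: int | None = None,
                 line: str | None = None):
        self.line_number = line_number
        self.line = line
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class OversizeRecordError(PdbLakeError):
    """An entry exceeds the maximum record size of the sequential store."""

    def __init__(self, message: str, index: int | None = None):
        self.index = index
        super().__init__(message)


class TrailingDataError(PdbLakeError):
    """Non-blank bytes follow the last END delimiter of a sequential file."""
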