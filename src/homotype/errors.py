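"""Exception hierarchy.

All data-level failures derive from :class:`HomotypeError` so the CLI can map
them to a single exit code; usage/parameter mistakes raise
:class:`ParameterError`.
"""


class HomotypeError(Exception):
    """Base class for all package-level errors."""


class ParameterError(HomotypeError, ValueError):
    """An argument value is outside its documented domain."""


class FastaFormatError(HomotypeError):
    """Input is not well-formed FASTA; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateIdError(HomotypeError):
    """Two records in one dataset share an identifier."""


class EmptyDatasetError(HomotypeError):
    """A non-empty dataset was required."""


class PatternSyntaxError(HomotypeError):
    """A PROSITE pattern string could not be parsed; carries token position."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"token {position}: {message}")


class TabularFormatError(HomotypeError):
    """A tabular hit file violates the 12-column contract."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ConfigurationError(HomotypeError):
    """The requested operation is inconsistent with the supplied data."""


class GenerationError(HomotypeError):
    """Synthetic-data rejection sampling failed to converge."""
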