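"""Exception hierarchy shared across the pipeline."""


class RelpaError(Exception):
    """Base class for all package errors."""


class ConfigError(RelpaError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(RelpaError):
    """Input data violates a precondition (too short, empty, degenerate)."""


class DomainError(RelpaError):
    """A scalar argument is outside its physical/definitional domain."""


class ContractError(RelpaError):
    """Caller broke an interface contract (e.g. feature-name mismatch)."""


class ConsistencyError(RelpaError):
    """Cross-file or cross-record inconsistency in a study dataset."""


class ParseError(RelpaError):
    """A malformed row or value in an on-disk file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
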