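"""Exception hierarchy shared across the package."""


class CtdnaMrdError(Exception):
    """Base class for all package errors."""


class FormatError(CtdnaMrdError):
    """A file is structurally malformed (e.g. a mandatory column is missing)."""


class RowError(CtdnaMrdError):
    """A single data row violates a type invariant.

    Attributes
    ----------
    row : int
        1-based data-row number (header excluded).
    message : str
        What was wrong.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        self.message = message
        super().__init__(f"row {row}: {message}")


class InvariantError(CtdnaMrdError):
    """A domain object was constructed with fields violating its invariants."""


class ConfigError(CtdnaMrdError):
    """An invalid configuration value (thresholds, rates, distribution parameters)."""


class DataError(CtdnaMrdError):
    """Inconsistent data handed to an operation (mixed participants, conflicting
    duplicate ddPCR calls, ...)."""


class UndefinedVafError(CtdnaMrdError):
    """VAF requested for a call with zero total read count."""
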