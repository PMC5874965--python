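"""Exception hierarchy shared across the package."""


class TomoSPCError(Exception):
    """Base class for all package errors."""


class QAParseError(TomoSPCError):
    """Raised when a QA log or experiment table cannot be parsed.

    Carries ``row_errors``: list of (line_number, message) for every offending
    row, so callers can report all problems at once.
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class EmptySelectionError(TomoSPCError):
    """No records matched the requested (unit, axis) selection."""


class InsufficientDataError(TomoSPCError):
    """Too few observations for the requested statistic."""


class DegenerateSampleError(TomoSPCError):
    """Sample has zero variance where dispersion is required."""


class DegenerateDesignError(TomoSPCError):
    """Regression design has no spread in the predictor."""


class ConfigError(TomoSPCError):
    """Invalid analysis configuration."""
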