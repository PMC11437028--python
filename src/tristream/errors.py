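"""Exception hierarchy shared across the package.

Two broad families matter operationally: configuration problems (bad
parameters, unknown keys, out-of-range perturbations) and data problems
(missing columns, empty series, degenerate profiles).  The CLI maps them
to exit codes 1 and 2 respectively.
"""


class TristreamError(Exception):
    """Base class for all package errors."""


class ConfigError(TristreamError):
    """Invalid configuration, parameter or option."""


class InvalidInputError(TristreamError):
    """A numerical input violates a precondition (non-finite, out of domain)."""


class DataError(TristreamError):
    """Malformed, missing or degenerate input data."""


class SchemaError(DataError):
    """An input table is missing required columns or has unparseable rows."""


class EmptyOutputError(DataError):
    """A QC or matchup stage produced an empty result."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"empty output after stage '{stage}'")


class DegenerateProfileError(DataError):
    """An irradiance profile cannot support the requested diagnostic."""


class OracleFailureError(TristreamError):
    """The numerical boundary-value oracle failed to converge."""


class InsufficientDataError(DataError):
    """Fewer valid wavelengths than the configured minimum."""
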