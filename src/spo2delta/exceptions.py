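"""Exception taxonomy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, data-shaped errors
(FormatError, EmptyInputError, SchemaError, ExtractionError) -> 3,
numerical/statistical failures (DegenerateInputError, NonIdentifiableError,
CalibrationRangeError) -> 4.
"""


class SpO2DeltaError(Exception):
    """Base class for all package errors."""


class ConfigError(SpO2DeltaError):
    """Invalid or inconsistent run configuration."""


class FormatError(SpO2DeltaError):
    """Input file could not be parsed."""


class EmptyInputError(FormatError):
    """Input file contained no samples."""


class SchemaError(SpO2DeltaError):
    """A table is missing required columns or has mismatched lengths."""


class ExtractionError(SpO2DeltaError):
    """No contiguous valid run of the requested duration exists."""

    def __init__(self, msg: str, longest_valid_run_s: int = 0):
        super().__init__(msg)
        self.longest_valid_run_s = longest_valid_run_s


class DegenerateInputError(SpO2DeltaError):
    """Input too short / too small for the requested computation."""


class NonIdentifiableError(SpO2DeltaError):
    """Model parameters cannot be identified (constant or collinear input)."""


class CalibrationRangeError(SpO2DeltaError):
    """Requested target lies outside the achievable range of the generator."""

    def __init__(self, msg: str, achievable_low: float, achievable_high: float):
        super().__init__(msg)
        self.achievable_low = achievable_low
        self.achievable_high = achievable_high
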