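"""Exception and warning types shared across the pipeline."""


class ValidationError(ValueError):
    """Input violates a structural contract (monotonicity, positivity, ...)."""


class RRParseError(ValidationError):
    """A beat-interval text file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UndefinedMetricError(ValueError):
    """A metric or correlation is undefined for this input (too short, constant)."""


class ConsistencyWarning(UserWarning):
    """A file's redundant columns disagree; derived values were kept."""


class ResolutionWarning(UserWarning):
    """The analysis window covers too few cycles of a band's lowest frequency."""
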