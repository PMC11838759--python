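"""Typed errors raised across the pipeline.

Every reader/stage failure is a subclass of :class:`SkingwasError` so callers
(and the CLI) can distinguish pipeline errors from programming errors.
"""


class SkingwasError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SkingwasError):
    """A file-level problem: missing column, too few columns, wrong header."""


class RowError(SkingwasError):
    """A row-level problem; carries the 1-based line number of the offending row."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class BuildMismatchError(SkingwasError):
    """Inputs carry different genome builds; mixing builds is a hard error."""


class DomainError(SkingwasError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateInputError(SkingwasError):
    """An input is structurally valid but makes the requested statistic undefined
    (empty background, constant predictor, separated outcome, ...)."""


class StageError(SkingwasError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
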