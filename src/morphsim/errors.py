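"""Exception types shared across the package."""


class MorphsimError(Exception):
    """Base class for all package errors."""


class ArgumentError(MorphsimError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(MorphsimError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero variance, constant map, too few observations)."""


class ValidationError(MorphsimError, ValueError):
    """A file or table failed structural validation; message itemizes offenders."""


class PipelineStageError(MorphsimError, RuntimeError):
    """A pipeline stage failed; outputs of earlier stages are left intact."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
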