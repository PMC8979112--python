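"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or type invariant."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
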