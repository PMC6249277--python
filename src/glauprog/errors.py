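"""Exception types raised across the package."""


class ValidationError(ValueError):
    """Input data or configuration violates a documented invariant."""


class SchemaError(ValidationError):
    """A CSV table does not match the expected column schema."""


class NotConvergedError(RuntimeError):
    """A mixed-model fit did not converge and results were requested."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending ids."""

    def __init__(self, stage: str, message: str, record_ids=()):
        self.stage = stage
        self.record_ids = list(record_ids)
        detail = f" [records: {', '.join(map(str, self.record_ids))}]" if self.record_ids else ""
        super().__init__(f"stage {stage!r}: {message}{detail}")
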