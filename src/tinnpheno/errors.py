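"""Exception hierarchy for the tinnpheno pipeline."""


class TinnphenoError(Exception):
    """Base class for all tinnpheno errors."""


class ConfigurationError(TinnphenoError):
    """A configuration value violates its invariants (names the offending field)."""


class DataValidationError(TinnphenoError):
    """An input table violates the data contract (names the offending record)."""


class StageError(TinnphenoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
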