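"""Exception hierarchy for the prioritization pipeline."""


class RecvarError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RecvarError):
    """Input violates the expected file format (e.g. a VCF without a GT field)."""


class ConsistencyError(RecvarError):
    """Cross-file inputs disagree (e.g. a VCF sample absent from the sample sheet)."""


class ValidationError(RecvarError):
    """A value violates a domain invariant (e.g. an allele frequency outside [0, 1])."""


class ConfigurationError(RecvarError):
    """A run configuration is unusable (e.g. control exclusion with no controls)."""


class UndefinedResultError(RecvarError):
    """The requested statistic is undefined for the given data (never a silent 0)."""


class StageError(RecvarError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
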