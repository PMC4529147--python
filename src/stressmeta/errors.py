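"""Exception hierarchy shared across the pipeline stages."""


class StressMetaError(Exception):
    """Base class for all package errors."""


class DomainError(StressMetaError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(StressMetaError, ValueError):
    """A configuration object fails validation."""


class CalibrationError(StressMetaError, RuntimeError):
    """A staircase failed to accumulate enough reversals for a threshold."""


class UndefinedAUCError(StressMetaError, ValueError):
    """Type-2 AUC is undefined (a participant has no errors or no corrects)."""

    def __init__(self, message: str, participant_id=None):
        super().__init__(message)
        self.participant_id = participant_id


class CohortSizeError(StressMetaError, ValueError):
    """Too few participants for a cohort-level operation."""


class AlignmentError(StressMetaError, ValueError):
    """Series that must share a common grid do not."""


class PairingError(StressMetaError, ValueError):
    """Repeated-measures rows cannot be paired."""


class PipelineError(StressMetaError, RuntimeError):
    """A pipeline stage failed; carries stage and participant context."""

    def __init__(self, message: str, stage: str | None = None, participant_id=None):
        super().__init__(message)
        self.stage = stage
        self.participant_id = participant_id
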