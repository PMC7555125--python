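"""Exception hierarchy for the e-nose pipeline."""


class EnoseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EnoseError):
    """Invalid configuration value or unparseable config file."""


class CohortValidationError(EnoseError):
    """One or more records violate the raw-record contract.

    Carries *all* violations found, not just the first, so a bad container
    can be diagnosed in one pass.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "cohort validation failed with %d violation(s):\n  %s"
            % (len(self.violations), "\n  ".join(self.violations))
        )


class SyncChannelError(EnoseError):
    """The two synchronization channels disagree on a heater transition."""

    def __init__(self, sample_index, message=None):
        self.sample_index = sample_index
        super().__init__(
            message
            or f"sync channels disagree on a transition at sample {sample_index}"
        )


class InsufficientCyclesError(EnoseError):
    """Fewer complete thermal cycles than the downstream pipeline needs."""


class DegenerateSignalError(EnoseError):
    """A ratio denominator hit the ADC floor; the record is unusable."""


class TrainingDivergenceError(EnoseError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch, learning_rate):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite training loss at epoch {epoch} "
            f"(learning_rate={learning_rate}); reduce the learning rate"
        )
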