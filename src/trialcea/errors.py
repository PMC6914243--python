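"""Exception hierarchy."""


class TrialCeaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrialCeaError):
    """A configuration value is invalid; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration for '{field}': {message}")


class CostingError(TrialCeaError):
    """Costing failed, e.g. a resource item without a unit price."""


class ModelError(TrialCeaError):
    """Model estimation failed (singular design, separation, ...)."""


class PipelineError(TrialCeaError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
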