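"""Exception hierarchy shared across the package."""


class DdaclError(Exception):
    """Base class for all package errors."""


class InputError(DdaclError):
    """Malformed or inconsistent user input (bad rows, NaNs, dimension mismatch)."""


class ConfigurationError(DdaclError):
    """Invalid configuration value or incompatible shapes in learned parameters."""


class AdapterError(DdaclError):
    """An encoder adapter failed on a specific entity."""

    def __init__(self, message: str, entity_id: str | None = None):
        super().__init__(message)
        self.entity_id = entity_id


class NumericError(DdaclError):
    """Non-finite values where finite ones are required."""


class TrainingError(DdaclError):
    """Training cannot proceed (e.g. no positive pairs)."""


class SamplingError(DdaclError):
    """Negative sampling or split construction is infeasible."""


class ThresholdError(DdaclError):
    """Threshold selection requires both classes present."""


class MetricError(DdaclError):
    """A metric is undefined for the given inputs."""
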