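"""Exception hierarchy for pharmqueue."""


class PharmQueueError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PharmQueueError, ValueError):
    """A rate, count or duration is outside its admissible range."""


class InstabilityError(PharmQueueError, ValueError):
    """Offered load meets or exceeds capacity (lambda >= s * mu); the
    steady-state quantity requested does not exist."""


class InconsistentObservationError(PharmQueueError, ValueError):
    """An observed quantity contradicts the model (e.g. observed mean
    number in system below the mean number in service)."""


class CalibrationError(PharmQueueError, ValueError):
    """No stable service rate reproduces the observed waiting time."""


class ConfigError(PharmQueueError, ValueError):
    """A simulation or network configuration is structurally invalid."""


class InsufficientDataError(PharmQueueError, ValueError):
    """Too few observations to run the requested estimate or test."""
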