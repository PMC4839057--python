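"""Exception types shared across the package."""


class HybridFermError(Exception):
    """Base class for package errors."""


class SimulationError(HybridFermError):
    """The ground-truth plant produced a non-physical state (negative or
    non-finite); usually a symptom of bad kinetics or too large a step."""


class IntegrationError(HybridFermError):
    """The hybrid-model integrator produced a non-finite state."""

    def __init__(self, message: str, time: float | None = None, weight_norm: float | None = None):
        super().__init__(message)
        self.time = time
        self.weight_norm = weight_norm


class StudyFormatError(HybridFermError):
    """A study directory or batch file is malformed."""
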