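"""Exception hierarchy for graftsim."""


class GraftsimError(Exception):
    """Base class for all graftsim errors."""


class ConfigurationError(GraftsimError):
    """Invalid model, controller, or experiment configuration."""


class SimulationError(GraftsimError):
    """Numerical integration failed (non-finite state)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ControllerError(GraftsimError):
    """Pre-setting or closed-loop control failed."""


class SafetyAbort(GraftsimError):
    """Safety interlock tripped during a regulated run."""

    def __init__(self, message: str, time: float, pressure: float):
        super().__init__(message)
        self.time = time
        self.pressure = pressure


class MeasurementError(GraftsimError):
    """Image measurement failed for a frame."""


class DetectionError(GraftsimError):
    """Cycle detection failed on a signal trace."""


class PipelineError(GraftsimError):
    """End-to-end analysis pipeline failed."""
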