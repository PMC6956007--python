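"""Exception hierarchy for fnspike."""


class FnSpikeError(Exception):
    """Base class for all fnspike errors."""


class InvalidParameterError(FnSpikeError, ValueError):
    """A neuron parameter vector violates its constraints."""


class InvalidStateError(FnSpikeError, ValueError):
    """A dynamical state (or input to the vector field) is non-finite."""


class InvalidStimulusError(FnSpikeError, ValueError):
    """A stimulus specification violates its constraints."""


class InvalidInputError(FnSpikeError, ValueError):
    """Generic invalid argument to a library operation."""


class SpikeAlignmentError(FnSpikeError, ValueError):
    """A spike time cannot be matched to a grid node within tolerance."""


class IntegrationDivergedError(FnSpikeError, RuntimeError):
    """The fixed-step integration blew up.

    Attributes
    ----------
    step : int
        Index of the grid step at which divergence was detected.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = int(step)
        super().__init__(message or f"integration diverged at step {step}")


class EstimationError(FnSpikeError, RuntimeError):
    """The bounded likelihood maximization failed to produce a finite optimum."""


class RecordingFormatError(FnSpikeError, ValueError):
    """A raw recording file is malformed (missing field, length mismatch, ...)."""


class ExperimentError(FnSpikeError, RuntimeError):
    """A repeated-estimation experiment could not produce a summary."""
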