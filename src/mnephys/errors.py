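"""Exception hierarchy for the mnephys pipeline.

Every analysis routine raises a subclass of :class:`MnephysError` so callers
(and the CLI) can separate scientific failure modes — a sweep that never
fires, a degenerate stimulus — from programming errors.
"""


class MnephysError(Exception):
    """Base class for all mnephys errors."""


class InvalidArgumentError(MnephysError, ValueError):
    """An argument is outside its documented domain (unknown preset, drug, ...)."""


class DegenerateInputError(MnephysError):
    """Input carries no usable signal (e.g. zero-amplitude current step)."""


class NotFoundError(MnephysError):
    """A required event was not found (e.g. no step reached rheobase).

    ``payload`` carries diagnostic context such as the maximum spike count
    observed across a step family.
    """

    def __init__(self, message, payload=None):
        super().__init__(message)
        self.payload = payload


class InsufficientFiringError(MnephysError):
    """Too few spikes to compute the requested firing statistic."""


class InvalidSweepError(MnephysError):
    """Sweep content violates the protocol contract (e.g. multiple spikes
    where exactly one is required)."""


class InvalidProtocolError(MnephysError):
    """Protocol definition is internally inconsistent or unsupported."""


class ProtocolMismatchError(MnephysError):
    """Two sweeps that must share a protocol differ; ``fields`` lists the
    mismatching attributes."""

    def __init__(self, message, fields=None):
        super().__init__(message)
        self.fields = fields or []


class SimulationError(MnephysError):
    """Numerical divergence during integration; names the parameter set."""


class SweepIOError(MnephysError):
    """Container violates the sweep schema, or the file is unreadable."""


class CapabilityError(MnephysError):
    """A requested optional capability (e.g. ABF/NWB reading) is unavailable."""
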