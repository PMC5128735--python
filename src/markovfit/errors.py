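"""Typed errors shared across the package."""


class MarkovFitError(Exception):
    """Base class for all package errors."""


class StiffnessOverflowError(MarkovFitError):
    """A transition rate overflowed (|ln r| too large to exponentiate).

    Carries the offending edge and the voltage at which it occurred so the
    caller (typically the annealer's cost evaluation) can reject the model.
    """

    def __init__(self, message, edge=None, voltage=None):
        super().__init__(message)
        self.edge = edge
        self.voltage = voltage


class DegenerateModelError(MarkovFitError):
    """The rate matrix is not a valid single-component generator
    (e.g. disconnected graph leading to rank deficiency beyond one)."""


class SimulationError(MarkovFitError):
    """Numerical failure during protocol simulation (expm overflow/NaN or
    ODE integration breakdown); carries context about protocol and sweep."""

    def __init__(self, message, protocol=None, sweep_value=None):
        super().__init__(message)
        self.protocol = protocol
        self.sweep_value = sweep_value


class FeatureUndefinedError(MarkovFitError):
    """A derived feature (e.g. a 10%-90% rise time) is undefined because the
    trace never crosses the required thresholds."""


class ProtocolError(MarkovFitError):
    """Protocol definition violates a structural rule (e.g. a sweep voltage
    within 1 mV of the reversal potential)."""


class SchemaError(MarkovFitError):
    """A model/protocol/dataset file violates its schema.

    ``location`` is a JSON-path-style string pointing at the offending field.
    """

    def __init__(self, message, location=None):
        if location is not None:
            message = f"{location}: {message}"
        super().__init__(message)
        self.location = location
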