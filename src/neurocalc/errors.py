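"""Exception hierarchy for the simulator."""


class NeurocalcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeurocalcError):
    """Invalid parameter value, unknown config key, or malformed config file."""


class StateDomainError(NeurocalcError):
    """A state combination outside the model's domain (e.g. a conserved pool
    driven negative)."""


class SolverError(NeurocalcError):
    """Integration failure; carries the last good time and state."""

    def __init__(self, message, t_last=None, state_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


class MetricsError(NeurocalcError):
    """A trajectory metric could not be computed from the given data."""
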