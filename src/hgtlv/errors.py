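"""Exception hierarchy."""


class HgtLvError(Exception):
    """Base class for all package errors."""


class ParameterError(HgtLvError, ValueError):
    """Invalid model or protocol parameter (wrong sign, shape, or range)."""


class InvariantError(HgtLvError, ValueError):
    """A state or trajectory violated a model invariant beyond tolerance."""


class StateError(HgtLvError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class IntegrationError(HgtLvError, RuntimeError):
    """The ODE integrator failed (step-size collapse or solver error)."""

    def __init__(self, message, *, state=None):
        super().__init__(message)
        self.state = state


class EnsembleError(HgtLvError, RuntimeError):
    """Too many per-draw failures inside a Monte-Carlo ensemble."""


class ConfigError(HgtLvError, ValueError):
    """Configuration document failed validation.

    ``errors`` collects every violation (field path + message), not just the
    first one encountered.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
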