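"""Exception types shared across the package."""


class TTFTimerError(Exception):
    """Base class for all package errors."""


class ValidationError(TTFTimerError):
    """A domain object (topology, parameter set, perturbation) is invalid."""


class ConfigError(TTFTimerError):
    """A configuration file is malformed or missing a required key."""


class SolverError(TTFTimerError):
    """Numerical integration failed for a specific parameter set."""

    def __init__(self, message: str, params_id: str | None = None):
        self.params_id = params_id
        super().__init__(message if params_id is None else f"{message} (params_id={params_id})")


class PerturbationError(ValidationError):
    """An in-silico perturbation is unknown, mistargeted, or stacked."""


class FixtureSearchError(TTFTimerError):
    """A fixture-circuit criterion was not met within the draw budget."""
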