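"""Exception types shared across the package."""


class ParameterValidationError(ValueError):
    """A game parameter violates its admissibility constraints."""


class ConfigurationError(ValueError):
    """A run/solver/scenario configuration is invalid."""


class IntegrationError(RuntimeError):
    """The ODE/DDE integrator failed to produce a valid trajectory."""
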