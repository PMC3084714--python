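"""Exception hierarchy for chemonav."""


class ChemonavError(Exception):
    """Base class for all chemonav errors."""


class ParameterError(ChemonavError, ValueError):
    """A kinetic or field parameter violates its invariants."""


class DomainError(ChemonavError, ValueError):
    """An input (ligand concentration, state component) is outside its domain."""


class StepSizeError(ChemonavError, RuntimeError):
    """The integration step produced a negative component beyond tolerance.

    Raised instead of silently clamping when the overshoot exceeds
    1e-9 * R_u; the remedy is a smaller ODE step.
    """


class ConfigurationError(ChemonavError, ValueError):
    """A scenario or environment is internally inconsistent (e.g. a ligand
    present in the environment has no kinetic parameter set)."""


class ScenarioNotFoundError(ConfigurationError, KeyError):
    """An unknown scenario preset name was requested."""
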