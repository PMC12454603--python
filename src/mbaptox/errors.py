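"""Exception hierarchy shared across the package."""


class MbaptoxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MbaptoxError):
    """A configuration document is missing keys or structurally invalid."""


class ParameterValidationError(ConfigurationError):
    """A parameter value or group violates a model invariant."""


class DomainError(MbaptoxError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class SolverError(MbaptoxError):
    """The ODE integrator failed or produced an unusable solution."""


class LookupKeyError(MbaptoxError, KeyError):
    """An unknown species/compartment/parameter was requested."""


class DegenerateFitError(MbaptoxError):
    """Input data cannot constrain the requested fit (e.g. all-zero velocities)."""


class NoTransitionError(DegenerateFitError):
    """A concentration-response dataset shows no transition to fit."""


class UnattainableTargetError(MbaptoxError):
    """A target blood concentration cannot be reached within the dose bracket."""
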