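"""Exception hierarchy for ptlasso."""


class PTLassoError(Exception):
    """Base class for all ptlasso errors."""


class InvalidNetworkError(PTLassoError):
    """A reaction network violates a structural invariant."""


class SimulationFailure(PTLassoError):
    """ODE integration produced a non-finite state.

    Carries the offending parameter vector so the sampler can map the
    failure to infinite energy instead of crashing.
    """

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = dict(params) if params else None


class SpecificationError(PTLassoError):
    """A caller-supplied specification is inconsistent (missing data point,
    unresolvable name, empty module, unequal chain lengths, ...)."""


class InvalidHyperparameterError(PTLassoError):
    """A prior/penalty hyperparameter is outside its admissible range."""


class DegenerateChainError(PTLassoError):
    """Convergence statistics are undefined (zero within-chain variance or
    singular within-chain covariance)."""


class InitializationError(PTLassoError):
    """Chain initialization failed to find a start point below the energy
    threshold. ``best_energy`` reports the best value seen."""

    def __init__(self, message, best_energy=None):
        super().__init__(message)
        self.best_energy = best_energy


class ConfigError(PTLassoError):
    """A run configuration file failed schema validation."""
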