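"""Exception types shared across the pipeline."""


class ReefcatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ReefcatchError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DomainError(ReefcatchError, ValueError):
    """Input violates a domain precondition (e.g. negative reef area)."""


class ClassificationError(ReefcatchError, ValueError):
    """Species or group cannot be classified (distinct from category 1)."""


class SchemaError(ReefcatchError, ValueError):
    """A CSV table does not match its declared schema."""


class DataError(ReefcatchError, ValueError):
    """A data table is structurally valid but unusable (e.g. all-gap CPUE)."""


class SimulationError(ReefcatchError, RuntimeError):
    """Forward simulation left the model's support (e.g. biomass floor)."""


class ConvergenceError(ReefcatchError, RuntimeError):
    """MCMC failed its convergence gate; diagnostics attached.

    Attributes
    ----------
    diagnostics : dict
        Per-parameter R-hat and effective sample sizes at failure.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
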