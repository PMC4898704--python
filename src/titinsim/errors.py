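"""Exception hierarchy."""


class TitinError(Exception):
    """Base class for all package errors."""


class ValidationError(TitinError, ValueError):
    """Invalid parameter, state, or input value."""


class DomainError(TitinError, ValueError):
    """Input outside the physical domain of a model (e.g. WLC beyond contour)."""


class SolverError(TitinError, RuntimeError):
    """A numerical solver failed to converge."""


class TimeStepError(TitinError, RuntimeError):
    """Per-step event probability exceeded the validity bound; reduce dt."""


class ConfigError(TitinError, ValueError):
    """Malformed or inconsistent run configuration."""
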