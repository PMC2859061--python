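"""Exception hierarchy.

Validation problems (bad parameters, bad config) and numerical failures
(root bracketing, integrator breakdown) are kept distinct so the CLI can
map them to different exit codes (2 and 3 respectively).
"""


class LipokinError(Exception):
    """Base class for all package errors."""


class ValidationError(LipokinError, ValueError):
    """A parameter or configuration value violates its invariant."""


class DomainError(LipokinError, ValueError):
    """An evaluation point lies outside the model's domain (r > R, t < 0, ...)."""


class NumericalError(LipokinError, RuntimeError):
    """A numerical procedure failed (bracketing, convergence, integration)."""


class ConfigError(ValidationError):
    """A run configuration is missing, ill-typed, or contains unknown keys."""
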