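"""Exception hierarchy for the carbon-homeostasis modelling package."""


class CHMError(Exception):
    """Base class for package errors."""


class ValidationError(CHMError, ValueError):
    """A parameter, state or data table violates its contract."""


class DomainError(ValidationError):
    """An argument lies outside its mathematical domain (e.g. time of day)."""


class ConfigurationError(CHMError, ValueError):
    """Solver or sampler configuration is inconsistent (e.g. step alignment)."""


class IntegrationError(CHMError, RuntimeError):
    """The numerical solution blew up (non-finite state)."""
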