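"""Exception hierarchy shared across the pipeline stages."""


class PropitsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PropitsError):
    """A configuration file or run configuration is unusable."""


class ValidationError(PropitsError):
    """An input value violates a documented precondition."""


class FitError(PropitsError):
    """A trend fit could not be performed (e.g. too few usable months)."""
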