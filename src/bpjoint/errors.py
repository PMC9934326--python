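"""Exception types shared across the package."""


class BpjointError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BpjointError, ValueError):
    """Invalid configuration values (probabilities, schedules, priors)."""


class SchemaError(BpjointError, ValueError):
    """Input tables violate the documented column/id contracts."""


class NumericalError(BpjointError, RuntimeError):
    """A numerical routine (root finder, decomposition) failed."""
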