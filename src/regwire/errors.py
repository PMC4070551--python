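"""Exception types shared across the pipeline stages."""


class RegwireError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RegwireError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DataValidationError(RegwireError, ValueError):
    """An input table violates a dataset invariant."""
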