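"""Exception hierarchy shared across the pipeline stages."""


class BlisscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(BlisscreenError):
    """A table is missing required columns or has the wrong dtypes."""


class ScreenValidationError(BlisscreenError):
    """A screen violates a structural invariant (e.g. missing monotherapy margin)."""


class DomainError(BlisscreenError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(BlisscreenError):
    """A run configuration is invalid or incomplete."""
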