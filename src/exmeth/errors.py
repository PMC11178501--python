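"""Exception hierarchy shared across the package."""


class ExmethError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExmethError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ExmethError):
    """Parsed data violates an invariant (counts, coordinates, config)."""


class ConfigError(ValidationError):
    """A configuration value or key is invalid."""
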