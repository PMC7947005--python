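"""Exception hierarchy shared across the package."""


class QuantNavError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(QuantNavError):
    """A position (or a derived position) lies outside the quantity space."""


class DomainError(QuantNavError):
    """A scalar argument is outside its valid domain."""


class GenerationError(QuantNavError):
    """A constrained trial generator exhausted its retry budget."""


class LogFormatError(QuantNavError):
    """A trajectory or response log violates its schema."""


class DesignError(QuantNavError):
    """A statistical design is unbalanced, degenerate or rank deficient."""


class ConfigError(QuantNavError):
    """A configuration file failed validation; message names the bad key."""
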