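"""Exception types shared across the package."""


class GenescapeError(Exception):
    """Base class for package errors."""


class CatalogFormatError(GenescapeError):
    """A gene-catalog file violates the expected tabular format."""


class AmbiguityError(GenescapeError):
    """Conflicting duplicate entries with no deduplication policy set."""


class ConfigError(GenescapeError):
    """Invalid configuration value."""


class UndefinedValueError(GenescapeError):
    """A statistic is undefined for the given input (recorded as missing, never as 0)."""
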