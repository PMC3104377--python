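"""Exception hierarchy shared across the package."""


class XbiasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XbiasError):
    """A file could not be parsed as the expected tabular format."""


class ValidationError(XbiasError):
    """Parsed data violate a domain invariant (duplicates, negatives, ...)."""


class UsageError(XbiasError):
    """An operation was called with arguments outside its contract."""


class ConfigError(XbiasError):
    """A run configuration is incomplete or inconsistent."""
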