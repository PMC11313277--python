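"""Exception hierarchy used across the package."""


class StrataTxError(Exception):
    """Base class for all package errors."""


class FormatError(StrataTxError):
    """A file on disk violates its format contract (bad field, bad line)."""


class ValidationError(StrataTxError):
    """An in-memory object violates an invariant of its type."""


class ConfigError(StrataTxError):
    """A configuration value is out of range or inconsistent."""
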