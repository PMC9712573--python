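"""Exception hierarchy shared across the package."""


class TikdError(Exception):
    """Base class for all package errors."""


class ConfigError(TikdError):
    """A configuration value is invalid; the message names the field."""


class DataError(TikdError):
    """An input record is malformed; the message locates the record."""


class IntegrityError(TikdError):
    """A packaged resource failed its checksum verification."""
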