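"""Exception hierarchy shared across the toolkit.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class MirAtlasError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(MirAtlasError):
    """Invalid configuration (bad thresholds, missing paths, ...)."""


class DataError(MirAtlasError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending record."""


class ValidationError(DataError):
    """A parsed record violates a domain invariant."""
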