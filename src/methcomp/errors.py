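"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its subclass
``ParseError``) to exit code 3.
"""


class MethcompError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MethcompError):
    """Invalid or inconsistent configuration."""


class DataError(MethcompError):
    """Input data violate an assumption of the analysis."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""
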