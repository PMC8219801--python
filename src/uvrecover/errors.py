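"""Exception hierarchy shared across the package.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class UVRecoverError(Exception):
    """Base class for package errors."""


class ConfigError(UVRecoverError):
    """Invalid configuration (bad thresholds, malformed config file...)."""


class DataError(UVRecoverError):
    """Invalid or inconsistent input data."""
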