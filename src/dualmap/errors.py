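"""Exception hierarchy.

ConfigurationError signals an invalid parameter set (exit code 2 in the CLI);
DataError signals malformed or inconsistent input data (exit code 3).
"""


class DualmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DualmapError):
    """An invalid configuration value; the message names the offending field."""


class DataError(DualmapError):
    """Malformed or mutually inconsistent input data."""
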