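"""Exception hierarchy shared across the package.

Validation/config/parse errors map to CLI exit code 2, everything else to 3.
"""


class CtflowError(Exception):
    """Base class for all package errors."""


class ValidationError(CtflowError):
    """Input data violates a documented contract (bad value, duplicate id...)."""


class ParseError(CtflowError):
    """A delimited file could not be parsed; message names row/column."""


class ConfigError(CtflowError):
    """A configuration value is out of range or inconsistent."""
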