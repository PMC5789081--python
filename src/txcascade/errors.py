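"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class TxCascadeError(Exception):
    """Base class for all package errors."""


class ConfigError(TxCascadeError):
    """Invalid or incomplete configuration (bad paths, bad parameter values)."""


class DataError(TxCascadeError):
    """Malformed or inconsistent input data."""
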