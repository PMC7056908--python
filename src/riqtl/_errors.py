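"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: ConfigError -> 2, DataError/FormatError -> 3.
"""


class RiqtlError(Exception):
    """Base class for all package errors."""


class ConfigError(RiqtlError):
    """A configuration value is missing, malformed or inconsistent."""


class DataError(RiqtlError):
    """Input data violates a contract (bad code, duplicate key, empty set...)."""


class FormatError(RiqtlError):
    """A file does not conform to its declared dialect."""
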