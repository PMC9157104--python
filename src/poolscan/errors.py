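"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError -> 3.
"""


class PoolscanError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PoolscanError):
    """Invalid parameter combination or run configuration."""


class FormatError(PoolscanError):
    """Malformed input file; message names the offending line where known."""


class ValidationError(PoolscanError):
    """Input data violates an operation's preconditions."""
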