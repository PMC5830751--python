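"""Exception hierarchy.

Config errors (bad parameters) and data errors (malformed inputs,
contract violations) are distinct so callers — in particular the CLI —
can map them to different exit codes.
"""


class EthogramError(Exception):
    """Base class for all package errors."""


class ConfigError(EthogramError):
    """Invalid configuration value (e.g. non-integer window length)."""


class DataError(EthogramError):
    """Malformed input data or violated data contract."""


class ParseError(DataError):
    """A file failed to parse; the message names the offending row."""
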