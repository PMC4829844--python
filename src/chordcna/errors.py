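"""Exception hierarchy.

Three classes map onto the CLI's distinct exit codes: configuration
problems (bad config file / flags), data problems (malformed or
inconsistent inputs), and everything else (internal errors).
"""


class ChordcnaError(Exception):
    """Base class for all package errors."""


class ConfigError(ChordcnaError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class DataError(ChordcnaError):
    """Malformed or inconsistent input data (bad BED line, genome mismatch...)."""
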