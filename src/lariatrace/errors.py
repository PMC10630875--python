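"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, InputError -> 3.
"""


class LariatraceError(Exception):
    """Base class for all package errors."""


class ConfigError(LariatraceError):
    """Invalid or inconsistent configuration / parameters."""


class InputError(LariatraceError):
    """Malformed or unreadable input data."""


class ValidationError(InputError):
    """Input parsed but violates a structural invariant."""
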