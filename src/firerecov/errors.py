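"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class FireRecovError(Exception):
    """Base class for all package errors."""


class ConfigError(FireRecovError):
    """A configuration value is outside its documented domain."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class DataError(FireRecovError):
    """Input data violates a structural requirement."""


class StateError(FireRecovError):
    """A cube arrived at an operation in the wrong processing state."""


class ConsistencyError(FireRecovError):
    """Two inputs that must come from the same processing chain do not."""
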