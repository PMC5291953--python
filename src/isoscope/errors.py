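class IsoscopeError(Exception):
    """Base class for pipeline errors."""


class ConfigError(IsoscopeError):
    """Invalid configuration (exit code 2 in the CLI)."""


class DataError(IsoscopeError):
    """Malformed or inconsistent input data (exit code 3 in the CLI)."""
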