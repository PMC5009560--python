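"""Exception hierarchy."""


class MetnetError(Exception):
    """Base class for all package errors."""


class FormatError(MetnetError, ValueError):
    """An input file violates its expected tabular format."""


class ConfigError(MetnetError, ValueError):
    """Invalid parameter combination or configuration value."""


class DomainError(MetnetError, ValueError):
    """An operation was called outside its mathematical domain."""


class ConvergenceError(MetnetError, RuntimeError):
    """Iterative propagation failed to reach the requested tolerance."""
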