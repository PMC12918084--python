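"""Exception hierarchy shared across the pipeline stages."""


class HealthMrpError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HealthMrpError):
    """Invalid covariate schema, or a value that does not belong to it."""


class AlignmentError(HealthMrpError):
    """Two objects that must share a cell index (or draw count) do not."""


class InfeasibleMarginsError(HealthMrpError):
    """A raking target puts mass on a level whose seed margin is all zero."""


class ConvergenceError(HealthMrpError):
    """Iterative proportional fitting did not reach tolerance."""


class DataError(HealthMrpError):
    """Malformed or degenerate input data (empty outcome, NaNs, one class)."""


class ConfigError(HealthMrpError):
    """Invalid pipeline / generator configuration."""
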