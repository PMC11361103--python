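"""Exception hierarchy for critdrift."""


class CritDriftError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CritDriftError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(CritDriftError, ValueError):
    """A configuration object is malformed or inconsistent."""


class DataValidationError(CritDriftError, ValueError):
    """Input data violate the trial-table schema; message names the offending rows."""


class UndefinedMetricError(CritDriftError, ValueError):
    """A metric is undefined for the given input (e.g. zero-variance sequence)."""
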