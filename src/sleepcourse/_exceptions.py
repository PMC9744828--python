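"""Exception hierarchy shared across the package."""


class SleepcourseError(ValueError):
    """Base class for all package errors."""


class ConfigError(SleepcourseError):
    """Invalid configuration (bad arity, out-of-range parameter, missing spec)."""


class DataError(SleepcourseError):
    """Input data violates a precondition (empty slice, missing level, ...)."""


class DegenerateDataError(DataError):
    """Data is formally valid but makes the requested statistic undefined
    (zero variance, rank-0 matrix, constant vector)."""
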