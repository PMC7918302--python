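"""Exception hierarchy shared across the package."""


class PtesleepError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PtesleepError):
    """Invalid or inconsistent user configuration."""


class UnsupportedFormatError(PtesleepError):
    """Input file is structurally valid but not supported (e.g. mixed
    per-channel sampling rates in one EDF)."""


class TooShortSignalError(PtesleepError):
    """Signal shorter than the filter warm-up requirement."""


class ModelDegeneracyError(PtesleepError):
    """Model cannot be fitted on the data provided (e.g. fewer events
    than mixture components)."""


class InsufficientReplicationError(PtesleepError):
    """A statistical test was requested with too few replicates."""


class UndefinedMetricError(PtesleepError):
    """A summary metric has an empty or zero denominator."""
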