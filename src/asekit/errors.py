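"""Exception types shared across the package."""


class AsekitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AsekitError, ValueError):
    """Invalid user-supplied values (counts, shapes, thresholds, tokens)."""


class DimensionError(ValidationError):
    """Array shape does not agree with the sample/variant axes."""


class DatasetStateError(AsekitError, RuntimeError):
    """Operation requires state the dataset does not have (e.g. resolved ref/alt)."""


class MalformedRecordError(AsekitError, ValueError):
    """An alignment record carries contradictory flags."""


class SimConfigError(ValidationError):
    """Simulation configuration is internally inconsistent or infeasible."""
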