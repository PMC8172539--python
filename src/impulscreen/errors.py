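"""Exception hierarchy shared across the package."""


class ImpulscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImpulscreenError):
    """A file does not conform to one of the documented dialects."""


class ValidationError(ImpulscreenError):
    """Parsed data violates a structural invariant (duplicates, negative
    expression, cells without annotation, time travel in event logs...)."""


class ConfigurationError(ImpulscreenError):
    """A run configuration is internally inconsistent or infeasible."""


class ClassificationError(ImpulscreenError):
    """An event log cannot be replayed through the trial state machine."""


class DegenerateSampleError(ImpulscreenError):
    """A statistic is undefined for the given sample (zero variance, n < 2)."""
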