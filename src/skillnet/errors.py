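"""Exception hierarchy shared across the pipeline stages."""


class SkillnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SkillnetError):
    """A configuration value is outside its documented range."""


class SamplingError(SkillnetError):
    """Sampling rate incompatible with the requested filtering."""


class InputError(SkillnetError):
    """A signal-level input violates a pre-condition (empty, too short...)."""


class CalibrationError(SkillnetError):
    """Invalid MVC calibration value (must be strictly positive)."""


class SchemaError(SkillnetError):
    """A table or file does not match the documented schema."""


class RosterMismatchError(SkillnetError):
    """Two objects that must share a participant roster do not."""


class UndefinedMetricError(SkillnetError):
    """Graph metric undefined for this input (too few nodes, no edges)."""


class UndefinedCorrelationError(SkillnetError):
    """Pearson/Spearman correlation undefined (constant input vector)."""


class IncompleteDataError(SkillnetError):
    """Required rows are missing for one or more participants."""
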