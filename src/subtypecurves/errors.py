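"""Exception hierarchy shared across the pipeline stages."""


class SubtypeCurvesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SubtypeCurvesError):
    """An invalid configuration value; the message names the offending field."""


class StructuralError(SubtypeCurvesError):
    """Inputs whose shapes, identifiers or label sets do not fit together."""


class NormalizationError(SubtypeCurvesError):
    """Size-factor estimation is impossible for the given count matrix."""


class TrainingError(SubtypeCurvesError):
    """A classifier cannot be trained on the provided data."""


class NumericalError(SubtypeCurvesError):
    """A numerically degenerate input (constant matrix, zero variance...)."""
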