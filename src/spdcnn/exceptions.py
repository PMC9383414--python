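"""Exception hierarchy shared across the package."""


class SPDCNNError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SPDCNNError):
    """Invalid parameter combination or malformed configuration."""


class DimensionError(SPDCNNError):
    """Shapes of trials, descriptors or statistics do not agree."""


class DataError(SPDCNNError):
    """Non-finite or otherwise unusable input data."""


class DegenerateTrialError(DataError):
    """A trial is too short to carry second-order statistics (T < 2)."""


class GeometryError(ConfigurationError):
    """Network input size does not survive the conv/pool reductions."""


class SamplingError(SPDCNNError):
    """An episodic task cannot be drawn from the available trials."""


class StateError(SPDCNNError):
    """Operation applied in the wrong pipeline state (e.g. double normalization)."""


class FormatError(SPDCNNError):
    """An artifact file is unreadable, corrupted or of an unknown version."""


class StateWarning(UserWarning):
    """Suspicious but recoverable pipeline state (e.g. unnormalized input)."""
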