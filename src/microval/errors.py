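"""Exception hierarchy shared across the package."""


class MicrovalError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(MicrovalError):
    """A volume file could not be read or its format is unsupported."""


class MetadataError(MicrovalError):
    """Required physical metadata (e.g. voxel size) is missing."""


class SchemaError(MicrovalError):
    """A tabular input does not have the expected columns."""


class ParseError(MicrovalError):
    """A tabular input has a value that cannot be parsed."""


class ParameterError(MicrovalError):
    """An argument is outside its admissible range."""


class SegmentationError(MicrovalError):
    """A segmentation step produced an empty or inconsistent result."""


class DegenerateDataError(MicrovalError):
    """Input data carry no usable signal (constant image, zero forces...)."""


class CalibrationError(MicrovalError):
    """Phantom calibration could not reach the requested target."""


class ConvergenceError(MicrovalError):
    """An iterative solver did not reach the requested tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class OutOfDomainError(MicrovalError):
    """A point lies outside the domain of an interpolant."""


class SampleSizeError(MicrovalError):
    """Too few data points for the requested statistic."""
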