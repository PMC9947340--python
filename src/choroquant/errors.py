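"""Exception hierarchy shared by all choroquant modules."""


class ChoroquantError(Exception):
    """Base class for all package errors."""


class FormatError(ChoroquantError):
    """A session directory or sidecar file is malformed or missing."""


class ValidationError(ChoroquantError):
    """An in-memory object violates one of its declared invariants."""


class ParameterError(ChoroquantError):
    """A parameter set is infeasible or out of its admissible domain."""


class DetectionError(ChoroquantError):
    """A layer detector found no admissible structure in the image."""


class FlatteningError(ChoroquantError):
    """Flattening would shift too much of a column out of the frame."""


class SegmentationError(ChoroquantError):
    """No admissible boundary path exists in the cost image."""


class EstimationError(ChoroquantError):
    """Too few paired observations to estimate the requested quantity."""


class UndefinedValueError(ChoroquantError):
    """A ratio is undefined (zero denominator); report as missing, not 0."""
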