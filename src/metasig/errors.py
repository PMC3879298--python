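"""Exception hierarchy shared across the pipeline.

``NotApplicableError`` is special: it marks (measure, k, order) combinations
that are mathematically undefined (e.g. an order-r centering with k < r+1) and
is rendered downstream as an NA matrix rather than a hard failure.
"""


class MetasigError(Exception):
    """Base class for all package errors."""


class FormatError(MetasigError):
    """A file does not parse under the expected format."""


class EmptyInputError(MetasigError):
    """An input (file or read set) contains no usable records."""


class DegenerateSampleError(MetasigError):
    """A sample is too small/empty for the requested operation."""


class NotApplicableError(MetasigError):
    """The requested (measure, k, order) combination is undefined (NA)."""


class LabelError(MetasigError):
    """Sample/leaf labels are duplicated or mismatched."""


class ParameterError(MetasigError):
    """A parameter is outside its documented domain."""


class UndefinedCorrelationError(MetasigError):
    """Correlation is undefined (constant input vector)."""
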