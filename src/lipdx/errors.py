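"""Exception hierarchy shared across the pipeline stages."""


class LipdxError(Exception):
    """Base class for all package errors."""


class FormatError(LipdxError):
    """Input raster is not a valid RGB image."""


class ParameterError(LipdxError):
    """A configuration parameter is out of its valid range."""


class DegenerateInputError(LipdxError):
    """Input is structurally valid but degenerate (constant image, empty mask, ...)."""


class SegmentationError(LipdxError):
    """The segmentation pipeline produced no usable lip mask."""
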