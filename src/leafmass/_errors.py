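"""Exception hierarchy shared across the pipeline."""


class LeafMassError(Exception):
    """Base class for all leafmass errors."""


class ValidationError(LeafMassError, ValueError):
    """Invalid user input: degenerate geometry, bad parameters, bad schema."""


class SegmentationError(LeafMassError):
    """Thresholding produced no usable foreground."""


class ImageIOError(LeafMassError, IOError):
    """An image file could not be read."""


class ParseError(LeafMassError, ValueError):
    """A textual specification (e.g. connection pairs) could not be parsed."""
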