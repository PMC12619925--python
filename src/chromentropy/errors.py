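"""Exception hierarchy.

Validation failures (bad inputs, malformed files, contract violations) all
derive from :class:`ChromentropyError` so the CLI can map them to a single
exit code distinct from I/O failures.
"""


class ChromentropyError(Exception):
    """Base class for all validation and contract errors."""


class EmptyROIError(ChromentropyError):
    """An ROI contains no pixels (empty mask or zero-total histogram)."""


class UnnormalizedDistributionError(ChromentropyError):
    """Probabilities do not sum to 1 within tolerance, or lie outside [0, 1]."""


class UnsupportedImageError(ChromentropyError):
    """Image has an unsupported channel count or bit depth (only 8-bit, 1 or 3 channels)."""


class InvalidPolygonError(ChromentropyError):
    """Polygon has fewer than 3 vertices or zero area."""


class RoiFormatError(ChromentropyError):
    """Byte stream is not a well-formed ImageJ .roi file."""


class UnsupportedRoiTypeError(RoiFormatError):
    """The .roi file encodes an ROI type other than polygon/freehand."""


class ProvenanceMismatchError(ChromentropyError):
    """Two entropy results were computed under different processing conventions."""
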