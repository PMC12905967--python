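"""Named exceptions raised across the package."""


class ConnTargetError(Exception):
    """Base class for all package errors."""


class NiftiFormatError(ConnTargetError):
    """File exists but is not a readable NIfTI-1 payload."""


class AffineError(ConnTargetError):
    """Volume affine is singular or non-finite."""


class GridMismatchError(ConnTargetError):
    """Operation combined volumes defined on different grids."""


class EmptyMaskError(ConnTargetError):
    """A non-empty mask was required."""


class ZeroVarianceError(ConnTargetError):
    """A correlation was requested on a constant series."""


class InvalidParameterError(ConnTargetError):
    """A numeric parameter violated its contract (radius, cutoff, fraction ...)."""
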