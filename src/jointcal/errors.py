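"""Exception hierarchy shared across the package."""


class JointcalError(ValueError):
    """Base class for all calibration-pipeline errors."""


class DegenerateGeometryError(JointcalError):
    """Raised when input geometry is too ill-conditioned to solve."""


class FrameMismatchError(JointcalError):
    """Raised when point data is expressed in an unexpected coordinate frame."""
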