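"""Exception hierarchy shared across the package."""


class UsnavError(Exception):
    """Base class for all package-specific errors."""


class FrameMismatchError(UsnavError):
    """Two frame-labelled objects were combined across incompatible frames."""


class BehindCameraError(UsnavError):
    """A point with non-positive camera-frame depth was projected."""


class DetectionFailureError(UsnavError):
    """The circle grid could not be (completely) detected, e.g. under occlusion."""


class DegenerateConfigurationError(UsnavError):
    """A point configuration does not constrain the requested estimate."""


class ConvergenceError(UsnavError):
    """An iterative refinement failed to converge within its iteration cap."""


class NoObjectError(UsnavError):
    """Segmentation produced an empty mask."""


class NonWatertightMeshError(UsnavError):
    """A mesh operation requiring a closed surface received an open mesh."""


class OutOfFieldError(UsnavError):
    """A query point fell outside the signed-distance-field grid."""
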