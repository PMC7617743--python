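"""Exception hierarchy shared across the pipeline stages."""


class CircumnautError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CircumnautError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class BehindCameraError(CircumnautError):
    """A 3D point lies at or behind the camera plane (camera-frame z <= 0)."""


class DegenerateGeometryError(CircumnautError):
    """Geometry admits no unique solution (zero baseline, coplanar poses...)."""


class NumericFailureError(CircumnautError):
    """An iterative numerical procedure failed to converge."""


class UntrackableStartError(CircumnautError):
    """The tracker seed point lies in a textureless image region."""


class UnfillableGapError(CircumnautError):
    """A trajectory gap exceeds the maximum fillable length."""


class UndefinedRotationError(CircumnautError):
    """Too many degenerate (near-zero radius) frames to define a rotation."""
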