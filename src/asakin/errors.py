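"""Exception hierarchy.

Input problems (bad files, mismatched shapes, invalid matrices) and
degenerate-motion problems (no rotation to estimate an axis from) are kept
distinct so the CLI can map them to different exit codes.
"""


class AsakinError(Exception):
    """Base class for all package errors."""


class InputError(AsakinError):
    """Invalid or inconsistent user input (shapes, files, parameters)."""


class InvalidPoseError(InputError):
    """Matrix is not a proper rotation within tolerance."""


class AlignmentError(InputError):
    """Two trajectories do not share timestamps/length."""


class DegenerateClusterError(InputError):
    """Marker cluster is collinear or too small to define a pose."""


class DegenerateMotionError(AsakinError):
    """Motion carries no usable rotation (all angular velocities ~ 0)."""


class InsufficientMotionError(DegenerateMotionError):
    """Too few samples above the angular-speed floor."""


class AmbiguousAxisError(DegenerateMotionError):
    """Leading eigenvalues of the angular covariance are degenerate."""


class GimbalLockWarning(UserWarning):
    """Euler extraction close to the middle-angle singularity."""
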