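"""Average screw axis (ASA) estimation and functional coordinate frames.

A segment's functional frame is built entirely from the joint's own
differential kinematics, so it needs no anatomical referencing:

* direction ``n_ASA``: unit eigenvector of the largest eigenvalue of the
  angular-velocity second-moment matrix ``C = (1/N) sum_i w_i w_i^T`` — the
  direction "most parallel" to the set of angular velocities;
* origin ``S_ASA``: weighted least-squares pseudo-intersection point of the
  instantaneous screw axes (ISAs);
* axes: ``e1 = n_ASA``, ``e2`` the second eigenvector of ``C`` (orthogonal
  complement direction of largest remaining angular-velocity variation),
  ``e3 = e1 x e2`` for right-handedness.

Sign conventions for the eigenvectors are fixed by frame-invariant
statistics of the twist series (sums of projections), so the assembled
frame is equivariant under any constant re-definition of the segment's
body-fixed coordinate system — which is what makes the downstream joint
angles invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AmbiguousAxisError,
    DegenerateMotionError,
    InputError,
    InsufficientMotionError,
)
from .se3 import Pose
from .twists import TwistTrajectory

__all__ = [
    "AngularCovariance",
    "ScrewAxisLine",
    "ASAFrame",
    "angular_covariance",
    "asa_direction",
    "instantaneous_screw_axes",
    "pseudo_intersection",
    "build_asa_frame",
]

DEFAULT_OMEGA_FLOOR = 0.10  # fraction of max |omega| below which ISAs are dropped
_RANK_RCOND = 1e-8          # relative singular-value cutoff for the normal matrix


@dataclass(frozen=True)
class AngularCovariance:
    """Second-moment matrix of the angular velocity, ``(1/N) sum w w^T``.

    Uncentred by construction: for an oscillating joint the mean angular
    velocity is near zero, and the dominant eigenvector of the raw second
    moment is the direction the rotation rate lives along regardless of its
    sign over the cycle.
    """

    C: np.ndarray          # (3, 3), (rad/s)^2
    n_samples: int

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (3, 3):
            raise InputError("covariance must be 3x3")
        if np.linalg.norm(C - C.T) > 1e-12 * max(1.0, np.linalg.norm(C)):
            raise InputError("covariance must be symmetric")
        object.__setattr__(self, "C", 0.5 * (C + C.T))

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and matching eigenvector columns."""
        vals, vecs = np.linalg.eigh(self.C)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]


@dataclass(frozen=True)
class ScrewAxisLine:
    """One instantaneous screw axis: unit direction ``u``, point ``q`` on the
    line closest to the expression-frame origin, rotation speed (rad/s)."""

    u: np.ndarray
    q: np.ndarray
    omega_norm: float


@dataclass
class ASAFrame:
    """Constant functional coordinate frame attached to one segment."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    eigenvalues: np.ndarray          # of C, descending, (rad/s)^2
    segment: str = "body"
    diagnostics: dict = field(default_factory=dict)

    @property
    def pose(self) -> Pose:
        """ASA frame as a pose w.r.t. the twist's expression frame."""
        return Pose(np.column_stack([self.e1, self.e2, self.e3]), self.origin)

    @property
    def axis_parallelism(self) -> float:
        """lambda1 / trace: 1 for a perfect hinge, 1/3 for isotropic motion."""
        s = float(np.sum(self.eigenvalues))
        return float(self.eigenvalues[0] / s) if s > 0 else float("nan")

    def to_dict(self) -> dict:
        d = dict(self.diagnostics)
        cond = d.get("condition_number")
        if cond is not None and not np.isfinite(cond):
            d["condition_number"] = None
        return {
            "segment": self.segment,
            "origin_m": self.origin.tolist(),
            "e1": self.e1.tolist(),
            "e2": self.e2.tolist(),
            "e3": self.e3.tolist(),
            "eigenvalues_rad2_per_s2": self.eigenvalues.tolist(),
            "axis_parallelism": self.axis_parallelism,
            "diagnostics": d,
        }


def angular_covariance(twists: TwistTrajectory) -> AngularCovariance:
    """Second-moment matrix of the angular-velocity series (no mean removal)."""
    w = twists.omega
    if len(twists) < 3:
        raise InputError("need at least 3 twist samples")
    # total rotation excursion below 1e-9 rad is numerical noise, not motion
    wmax = float(np.max(np.linalg.norm(w, axis=1)))
    duration = float(twists.times[-1] - twists.times[0])
    if wmax * max(duration, 1e-300) < 1e-9:
        raise DegenerateMotionError(
            f"motion is degenerate: peak rotation excursion ~ {wmax * duration:.1e} rad"
        )
    return AngularCovariance(w.T @ w / len(twists), len(twists))


def _signed(vec: np.ndarray, proj: np.ndarray, cubic_first: bool) -> np.ndarray:
    """Fix an eigenvector's sign from frame-invariant statistics of the
    angular-velocity projections onto it.

    For the main axis the net rotation ``sum w·e`` decides; a joint that
    flexes and returns has near-zero net rotation, so the fallback is the
    integrated excursion (sum of the cumulative rotation angle about the
    axis), which is positive when the joint spends the cycle rotated towards
    +e.  Both statistics depend only on the scalar series ``w·e``, so the
    convention survives any constant re-definition of the body frames.
    """
    if cubic_first:
        s = float(np.sum(proj**3))
        if s == 0.0:
            s = float(proj[np.argmax(np.abs(proj))])
    else:
        s = float(np.sum(proj))
        if abs(s) < 1e-2 * np.sum(np.abs(proj)):
            excursion = np.cumsum(proj)
            s = float(np.sum(excursion - excursion[0]))
            if s == 0.0:
                s = float(np.sum(proj**3))
    return -vec if s < 0 else vec


def asa_direction(C: AngularCovariance, twists: TwistTrajectory) -> np.ndarray:
    """Unit ASA direction: dominant eigenvector of C, sign such that the
    angular velocities point along it on aggregate (``sum w·n >= 0``)."""
    vals, vecs = C.eigendecomposition()
    if vals[0] <= 0.0:
        raise DegenerateMotionError("angular covariance has no positive eigenvalue")
    if vals[0] - vals[1] <= 1e-12 * vals[0]:
        raise AmbiguousAxisError(
            f"two leading eigenvalues are degenerate ({vals[0]:.3e}, {vals[1]:.3e}); "
            "no dominant rotation axis"
        )
    e1 = vecs[:, 0]
    return _signed(e1, twists.omega @ e1, cubic_first=False)


def instantaneous_screw_axes(
    twists: TwistTrajectory, omega_floor: float = DEFAULT_OMEGA_FLOOR
) -> list[ScrewAxisLine]:
    """Per-sample ISA lines, skipping low-angular-speed samples.

    ``u = w/|w|`` and ``q = (w x v)/|w|^2`` (the axis point closest to the
    expression-frame origin).  Samples with ``|w|`` below ``omega_floor``
    times the series maximum are excluded: ``q`` diverges as ``|w| -> 0``.
    """
    norms = np.linalg.norm(twists.omega, axis=1)
    wmax = float(norms.max(initial=0.0))
    if wmax <= 0.0:
        raise DegenerateMotionError("all angular velocities are zero")
    keep = norms >= omega_floor * wmax
    if int(keep.sum()) < 3:
        raise InsufficientMotionError(
            f"only {int(keep.sum())} samples above the angular-speed floor"
        )
    lines = []
    for w, v, nrm in zip(twists.omega[keep], twists.v[keep], norms[keep]):
        u = w / nrm
        q = np.cross(w, v) / nrm**2
        lines.append(ScrewAxisLine(u, q, float(nrm)))
    return lines


def pseudo_intersection(
    lines: list[ScrewAxisLine],
) -> tuple[np.ndarray, dict]:
    """Weighted least-squares pseudo-intersection point of a set of lines.

    Minimises ``sum_i w_i dist(S, line_i)^2`` with weights ``w_i = |omega_i|^2``
    via the normal equations ``sum w (I - u u^T) S = sum w (I - u u^T) q``.
    For near-parallel axes the normal matrix drops to rank 2 and any point on
    the common axis is optimal; the pseudo-inverse then returns the
    minimum-norm solution and a rank-deficiency flag is set.  The weights
    cancel the ``1/|omega|^2`` noise amplification in the axis points.
    """
    if len(lines) < 2:
        raise InputError("need at least 2 screw axes")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ln in lines:
        P = (np.eye(3) - np.outer(ln.u, ln.u)) * ln.omega_norm**2
        A += P
        b += P @ ln.q
    vals = np.linalg.eigvalsh(A)
    rank = int(np.sum(vals > _RANK_RCOND * vals[-1]))
    if rank < 2:
        raise DegenerateMotionError(
            "screw-axis pseudo-intersection is degenerate (rank < 2)"
        )
    S = np.linalg.pinv(A, rcond=_RANK_RCOND) @ b
    cond = float(vals[-1] / vals[0]) if vals[0] > 0 else float("inf")
    return S, {
        "condition_number": cond,
        "rank": rank,
        "rank_deficient": rank < 3,
        "n_lines": len(lines),
    }


def build_asa_frame(
    twists: TwistTrajectory, omega_floor: float = DEFAULT_OMEGA_FLOOR
) -> ASAFrame:
    """Assemble the functional ASA frame from one segment's twist series."""
    C = angular_covariance(twists)
    vals, vecs = C.eigendecomposition()
    e1 = asa_direction(C, twists)
    e2 = _signed(vecs[:, 1], twists.omega @ vecs[:, 1], cubic_first=True)
    # re-orthogonalise against e1 (guards against round-off in eigh)
    e2 = e2 - (e2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    lines = instantaneous_screw_axes(twists, omega_floor=omega_floor)
    origin, diag = pseudo_intersection(lines)
    diag["excluded_samples"] = len(twists) - len(lines)
    diag["omega_floor"] = omega_floor
    return ASAFrame(
        origin=origin,
        e1=e1,
        e2=e2,
        e3=e3,
        eigenvalues=vals,
        segment=twists.frame,
        diagnostics=diag,
    )
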