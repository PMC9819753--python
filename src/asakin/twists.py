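"""Relative pose trajectory and screw twists by numerical differentiation.

The joint's differential kinematics is the relative screw twist of the
tibia w.r.t. the femur.  From the relative pose series ``T(t)`` it is read
off the matrix products

    [w_fm]x  v_fm          [w_tb]x  v_tb
    [  0      0 ] = Tdot T^-1,  [  0   0 ] = T^-1 Tdot

so the same physical twist is expressed either in the femur frame or in the
tibia frame.  Differentiation is entry-wise second-order finite differences
on the homogeneous matrices: central in the interior, 3-point one-sided at
the two endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import AlignmentError, InputError
from .se3 import PoseTrajectory

__all__ = [
    "TwistSample",
    "TwistTrajectory",
    "relative_pose_trajectory",
    "differentiate_pose_trajectory",
    "extract_twists",
    "relative_twists",
]


@dataclass(frozen=True)
class TwistSample:
    """One screw-twist sample: angular velocity ``omega`` (rad/s), linear
    velocity ``v`` (m/s) of the expression-frame origin, frame label, time."""

    omega: np.ndarray
    v: np.ndarray
    frame: str
    time: float


@dataclass
class TwistTrajectory:
    """Screw-twist time series expressed in a single named frame."""

    times: np.ndarray
    omega: np.ndarray  # (n, 3) rad/s
    v: np.ndarray      # (n, 3) m/s
    frame: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.omega = np.asarray(self.omega, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = self.times.size
        if self.omega.shape != (n, 3) or self.v.shape != (n, 3):
            raise InputError("twist component shapes do not match timestamps")
        if not (np.all(np.isfinite(self.omega)) and np.all(np.isfinite(self.v))):
            raise InputError("twist contains non-finite components")

    def __len__(self) -> int:
        return self.times.size

    @property
    def samples(self) -> list[TwistSample]:
        return [
            TwistSample(self.omega[i], self.v[i], self.frame, float(self.times[i]))
            for i in range(len(self))
        ]

    def to_frame(self) -> str:
        return self.frame


def relative_pose_trajectory(
    fm: PoseTrajectory, tb: PoseTrajectory
) -> PoseTrajectory:
    """Per-sample relative pose ``inv(T_0fm) @ T_0tb`` of {tb} w.r.t. {fm}."""
    if len(fm) != len(tb):
        raise AlignmentError(f"length mismatch: {len(fm)} vs {len(tb)}")
    if np.max(np.abs(fm.times - tb.times)) > 1e-9:
        raise AlignmentError("segment trajectories have different timestamps")
    RfT = np.swapaxes(fm.Rs, 1, 2)
    Rs = RfT @ tb.Rs
    ps = np.einsum("nij,nj->ni", RfT, tb.ps - fm.ps)
    return PoseTrajectory(
        fm.times.copy(), Rs, ps, (fm.frame_labels[1], tb.frame_labels[1])
    )


def differentiate_pose_trajectory(
    traj: PoseTrajectory, smooth_window: int | None = None
) -> np.ndarray:
    """Entry-wise time derivative of the homogeneous matrices, shape (n, 4, 4).

    Central differences at interior samples, 3-point one-sided stencils at
    the endpoints; the bottom row derivative is exactly zero.  Optional
    ``smooth_window`` applies a quadratic Savitzky-Golay smoother to every
    matrix entry before differencing (off by default: the method is defined
    on unfiltered poses).
    """
    dt = traj.uniform_dt()
    T = traj.matrices()
    if smooth_window is not None:
        if smooth_window < 5 or smooth_window % 2 == 0:
            raise InputError("smooth_window must be an odd integer >= 5")
        flat = savgol_filter(T.reshape(len(traj), 16), smooth_window, 2, axis=0)
        T = flat.reshape(len(traj), 4, 4)
    dT = np.empty_like(T)
    dT[1:-1] = (T[2:] - T[:-2]) / (2.0 * dt)
    dT[0] = (-3.0 * T[0] + 4.0 * T[1] - T[2]) / (2.0 * dt)
    dT[-1] = (3.0 * T[-1] - 4.0 * T[-2] + T[-3]) / (2.0 * dt)
    dT[:, 3, :] = 0.0
    return dT


def _skew_project(W: np.ndarray) -> np.ndarray:
    """Angular-velocity vector from the antisymmetric part of a 3x3 block.

    The block is skew-symmetric only up to differencing error; (A - A^T)/2
    makes the extraction well-defined.
    """
    W = 0.5 * (W - np.swapaxes(W, 1, 2))
    return np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)


def extract_twists(
    rel: PoseTrajectory, deriv: np.ndarray
) -> tuple[TwistTrajectory, TwistTrajectory]:
    """Relative screw twist expressed in each segment frame.

    Femur-frame twist from ``Tdot @ inv(T)``, tibia-frame twist from
    ``inv(T) @ Tdot``, where ``T`` is the relative pose of {tb} w.r.t. {fm}.
    The linear velocities are assembled from ``pdot`` and the projected
    angular velocity (``v_fm = pdot - w_fm x p``, ``v_tb = R^T pdot``) so the
    symmetric differencing error removed from ``w`` cannot re-enter ``v``.
    """
    T = rel.matrices()
    deriv = np.asarray(deriv, dtype=float)
    if deriv.shape != T.shape:
        raise InputError(f"derivative shape {deriv.shape} != {T.shape}")
    RsT = np.swapaxes(rel.Rs, 1, 2)
    pdot = deriv[:, :3, 3]
    # Tdot T^-1 block: Rdot R^T;  T^-1 Tdot block: R^T Rdot
    w_fm = _skew_project(deriv[:, :3, :3] @ RsT)
    w_tb = _skew_project(RsT @ deriv[:, :3, :3])
    v_fm = pdot - np.cross(w_fm, rel.ps)
    v_tb = np.einsum("nij,nj->ni", RsT, pdot)
    ref, mov = rel.frame_labels
    return (
        TwistTrajectory(rel.times.copy(), w_fm, v_fm, ref),
        TwistTrajectory(rel.times.copy(), w_tb, v_tb, mov),
    )


def relative_twists(
    fm: PoseTrajectory, tb: PoseTrajectory, smooth_window: int | None = None
) -> tuple[TwistTrajectory, TwistTrajectory]:
    """Convenience pipeline: relative poses -> derivative -> both twists."""
    rel = relative_pose_trajectory(fm, tb)
    deriv = differentiate_pose_trajectory(rel, smooth_window=smooth_window)
    return extract_twists(rel, deriv)
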