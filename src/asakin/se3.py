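"""Rigid-motion primitives: poses, trajectories, Euler angles, marker fits.

Conventions
-----------
A :class:`Pose` maps moving-frame coordinates to reference-frame
coordinates: ``x_ref = R @ x_body + p``.  The pose of segment {tb} in the
lab {0} is therefore the matrix usually written ``T_0tb``, and the relative
pose of {tb} w.r.t. {fm} is ``inv(T_0fm) @ T_0tb``.

Euler angles are intrinsic (moving-axes) rotations, reported in degrees.
Positions are metres, timestamps seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import (
    DegenerateClusterError,
    GimbalLockWarning,
    InputError,
    InvalidPoseError,
)

EULER_SEQUENCES = ("XYZ", "ZYX")

_STRICT_TOL = 1e-9      # below this the matrix is accepted as-is
_REPAIR_TOL = 1e-6      # up to this it is projected to the nearest rotation


def _rotation_defect(R: np.ndarray) -> float:
    return float(np.linalg.norm(R.T @ R - np.eye(3)))


@dataclass(frozen=True)
class Pose:
    """Rigid pose: rotation ``R`` (3x3) and origin position ``p`` (metres)."""

    R: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        p = np.asarray(self.p, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidPoseError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(p)):
            raise InvalidPoseError("pose contains non-finite entries")
        defect = _rotation_defect(R)
        det = float(np.linalg.det(R))
        if defect > _REPAIR_TOL or det <= 0:
            raise InvalidPoseError(
                f"not a proper rotation (orthonormality defect {defect:.2e}, det {det:.6f})"
            )
        if defect > _STRICT_TOL:
            # nearest rotation by polar decomposition
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
            if np.linalg.det(R) < 0:
                raise InvalidPoseError("projection yielded a reflection")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "p", p)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix with bottom row (0, 0, 0, 1)."""
        T = np.eye(4)
        T[:3, :3] = self.R
        T[:3, 3] = self.p
        return T

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "Pose":
        T = np.asarray(T, dtype=float)
        if T.shape != (4, 4):
            raise InvalidPoseError(f"homogeneous matrix must be 4x4, got {T.shape}")
        if not np.allclose(T[3], (0.0, 0.0, 0.0, 1.0), atol=1e-12):
            raise InvalidPoseError("bottom row must be (0, 0, 0, 1)")
        return cls(T[:3, :3], T[:3, 3])


def make_pose(R: np.ndarray, p: np.ndarray) -> Pose:
    """Validated pose constructor (repairs tiny orthonormality defects)."""
    return Pose(R, p)


def compose(a: Pose, b: Pose) -> Pose:
    """Pose product ``a ∘ b`` (apply ``b`` first in a's moving frame)."""
    return Pose(a.R @ b.R, a.R @ b.p + a.p)


def inverse(a: Pose) -> Pose:
    return Pose(a.R.T, -a.R.T @ a.p)


# ---------------------------------------------------------------------------
# Euler angles


def _check_sequence(seq: str) -> str:
    if seq not in EULER_SEQUENCES:
        raise InputError(f"Euler sequence must be one of {EULER_SEQUENCES}, got {seq!r}")
    return seq


def euler_from_matrix_stack(Rs: np.ndarray, seq: str) -> np.ndarray:
    """Intrinsic Euler angles (degrees) for a stack of rotation matrices."""
    _check_sequence(seq)
    rot = Rotation.from_matrix(np.asarray(Rs, dtype=float))
    with warnings.catch_warnings():
        # scipy's convention at gimbal lock (third angle zero, full rotation
        # on the first) is exactly ours; we re-emit a clearer warning below.
        warnings.simplefilter("ignore")
        ang = rot.as_euler(seq, degrees=True)
    ang = np.atleast_2d(ang)
    near_lock = np.abs(np.abs(ang[:, 1]) - 90.0) < 0.5
    if np.any(near_lock):
        warnings.warn(
            f"{int(near_lock.sum())} sample(s) within 0.5 deg of gimbal lock for "
            f"sequence {seq}; third angle set to 0 there",
            GimbalLockWarning,
            stacklevel=2,
        )
    return ang


def euler_from_pose(a: Pose, seq: str) -> np.ndarray:
    """Three intrinsic Euler angles (degrees) of the pose's rotation."""
    return euler_from_matrix_stack(a.R[np.newaxis], seq)[0]


def pose_from_euler(angles, seq: str, p=(0.0, 0.0, 0.0)) -> Pose:
    _check_sequence(seq)
    R = Rotation.from_euler(seq, np.asarray(angles, dtype=float), degrees=True).as_matrix()
    return Pose(R, np.asarray(p, dtype=float))


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class PoseTrajectory:
    """Time series of rigid poses of ``frame_labels[1]`` w.r.t. ``frame_labels[0]``.

    Orientation and position are stored as stacked arrays ``Rs`` (n, 3, 3)
    and ``ps`` (n, 3) for vectorised downstream work.
    """

    times: np.ndarray
    Rs: np.ndarray
    ps: np.ndarray
    frame_labels: tuple[str, str] = ("0", "body")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.Rs = np.asarray(self.Rs, dtype=float)
        self.ps = np.asarray(self.ps, dtype=float)
        n = self.times.size
        if n < 3:
            raise InputError(f"trajectory needs >= 3 samples, got {n}")
        if self.Rs.shape != (n, 3, 3) or self.ps.shape != (n, 3):
            raise InputError(
                f"shape mismatch: times {n}, Rs {self.Rs.shape}, ps {self.ps.shape}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise InputError("timestamps must be strictly increasing")
        # validate rotations in bulk (projection handled per-pose if needed)
        defects = np.linalg.norm(
            np.einsum("nij,nik->njk", self.Rs, self.Rs) - np.eye(3), axis=(1, 2)
        )
        if np.any(defects > _STRICT_TOL):
            self.Rs = np.stack(
                [Pose(R, p).R for R, p in zip(self.Rs, self.ps)]
            )

    def __len__(self) -> int:
        return self.times.size

    def pose(self, i: int) -> Pose:
        return Pose(self.Rs[i], self.ps[i])

    @property
    def poses(self) -> list[Pose]:
        return [self.pose(i) for i in range(len(self))]

    def matrices(self) -> np.ndarray:
        """Stack of homogeneous matrices, shape (n, 4, 4)."""
        T = np.tile(np.eye(4), (len(self), 1, 1))
        T[:, :3, :3] = self.Rs
        T[:, :3, 3] = self.ps
        return T

    @classmethod
    def from_poses(cls, times, poses, frame_labels=("0", "body")) -> "PoseTrajectory":
        return cls(
            np.asarray(times, dtype=float),
            np.stack([p.R for p in poses]),
            np.stack([p.p for p in poses]),
            tuple(frame_labels),
        )

    def uniform_dt(self, rtol: float = 1e-9) -> float:
        """Sampling interval; raises if spacing is not uniform within rtol."""
        dts = np.diff(self.times)
        dt = float(dts[0])
        if np.max(np.abs(dts - dt)) > rtol * dt:
            raise InputError("trajectory is not uniformly sampled; resample first")
        return dt


@dataclass
class MarkerTrajectory:
    """Per-frame 3D positions of a labelled marker cluster on one segment."""

    marker_ids: list[str]
    positions: np.ndarray  # (n, M, 3), metres
    times: np.ndarray
    segment: str = "body"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float)
        n, m = self.times.size, len(self.marker_ids)
        if m < 3:
            raise DegenerateClusterError(f"need >= 3 markers, got {m}")
        if self.positions.shape != (n, m, 3):
            raise InputError(
                f"positions shape {self.positions.shape} != ({n}, {m}, 3)"
            )
        centred = self.positions - self.positions.mean(axis=1, keepdims=True)
        # collinear cluster <=> centred matrix has rank < 2; any 3 points are
        # coplanar, so the test is on the second singular value
        s = np.linalg.svd(centred, compute_uv=False)
        if np.any(s[:, 1] <= 1e-9):
            bad = int(np.argmax(s[:, 1] <= 1e-9))
            raise DegenerateClusterError(
                f"markers collinear at sample {bad} (2nd singular value {s[bad, 1]:.2e} m)"
            )

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Marker-based pose estimation (Kabsch / SVD with determinant correction)


def pose_from_markers(
    reference_cluster: np.ndarray, observed_cluster: np.ndarray
) -> tuple[Pose, float]:
    """Least-squares rigid transform mapping the reference cluster onto the
    observed one.

    Solves ``min_{R,p} sum_k |R a_k + p - b_k|^2`` by SVD of the centred
    cross-covariance, with the determinant sign correction that guarantees a
    proper rotation even for reflected/noisy clusters.  Returns the pose and
    the RMS marker residual (metres).
    """
    a = np.asarray(reference_cluster, dtype=float)
    b = np.asarray(observed_cluster, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"cluster shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise InputError(f"clusters must be (M>=3, 3), got {a.shape}")
    for name, cl in (("reference", a), ("observed", b)):
        s = np.linalg.svd(cl - cl.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9:
            raise DegenerateClusterError(f"{name} cluster is collinear")
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    H = (a - ac).T @ (b - bc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    p = bc - R @ ac
    residual = float(np.sqrt(np.mean(np.sum((a @ R.T + p - b) ** 2, axis=1))))
    return Pose(R, p), residual


def poses_from_markers(
    traj: MarkerTrajectory,
    reference_cluster: np.ndarray | None = None,
    lab_frame: str = "0",
) -> tuple[PoseTrajectory, np.ndarray]:
    """Segment pose trajectory from a marker cluster.

    The body-fixed technical frame is defined by the cluster at the first
    time sample unless ``reference_cluster`` is given; the downstream ASA
    method is invariant to this (arbitrary) choice.
    """
    ref = traj.positions[0] if reference_cluster is None else np.asarray(reference_cluster)
    out_R = np.empty((len(traj), 3, 3))
    out_p = np.empty((len(traj), 3))
    res = np.empty(len(traj))
    for i in range(len(traj)):
        pose, res[i] = pose_from_markers(ref, traj.positions[i])
        out_R[i], out_p[i] = pose.R, pose.p
    return (
        PoseTrajectory(traj.times, out_R, out_p, (lab_frame, traj.segment)),
        res,
    )


# ---------------------------------------------------------------------------
# Resampling


def resample_trajectory(traj: PoseTrajectory, n: int) -> PoseTrajectory:
    """Resample to ``n`` uniform samples spanning the original time range.

    Orientations are interpolated on the rotation manifold (shortest-path
    quaternion slerp), positions linearly; endpoints are preserved exactly.
    """
    if n < 3:
        raise InputError(f"need n >= 3 resampling points, got {n}")
    t_new = np.linspace(traj.times[0], traj.times[-1], n)
    t_new[0], t_new[-1] = traj.times[0], traj.times[-1]
    slerp = Slerp(traj.times, Rotation.from_matrix(traj.Rs))
    Rs = slerp(t_new).as_matrix()
    ps = np.column_stack(
        [np.interp(t_new, traj.times, traj.ps[:, k]) for k in range(3)]
    )
    return PoseTrajectory(t_new, Rs, ps, traj.frame_labels)
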