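"""Synthetic two-segment knee motion generator with known ground truth.

Emulates the statistical structure the ASA method assumes in a gait trial:
hinge-dominant relative rotation of tibia w.r.t. femur (a gait-like flexion
profile about a fixed femur-frame axis), small out-of-plane rotations, and
both segments moving in the laboratory frame.  Optionally rigid marker
clusters with isotropic noise are attached to drive the marker-level
pipeline end to end.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .se3 import MarkerTrajectory, PoseTrajectory

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_knee",
    "attach_marker_clusters",
    "DEFAULT_FEMUR_CLUSTER",
    "DEFAULT_TIBIA_CLUSTER",
]

# thigh / shank technical clusters (metres, segment frame): non-coplanar
# quads with ~15 cm spread, the scale of clinical marker plates (cluster
# size sets how 1 mm of marker noise maps to orientation noise)
DEFAULT_FEMUR_CLUSTER = np.array(
    [
        [0.04, -0.12, 0.05],
        [0.19, -0.16, 0.04],
        [0.06, -0.30, 0.08],
        [0.14, -0.20, 0.17],
    ]
)
DEFAULT_TIBIA_CLUSTER = np.array(
    [
        [0.03, -0.08, 0.04],
        [0.17, -0.12, 0.03],
        [0.05, -0.26, 0.07],
        [0.12, -0.16, 0.16],
    ]
)


@dataclass
class WorldMotion:
    """Parametric rigid motion of the femur in the lab over one cycle:
    forward progression plus smooth translational and rotational sinusoids."""

    translation_amplitude: float = 1.2   # forward progression per cycle, m
    rotation_amplitude: float = 10.0     # deg


@dataclass
class SimulationConfig:
    n_samples: int = 101
    cycle_duration: float = 1.0                    # s
    flexion_amplitude: float = 56.2                # deg, max - min of the profile
    flexion_profile: str = "gait_double_hump"      # or "raised_cosine"
    out_of_plane_amplitude: float = 2.0            # deg
    axis_direction: tuple = (0.0, 0.0, 1.0)        # femur frame (z = knee axis)
    axis_point: tuple = (0.03, 0.02, 0.0)          # m, femur frame
    tibia_offset: tuple = (0.0, -0.40, 0.0)        # tibia origin at rest, m
    femur_world_motion: WorldMotion = field(default_factory=WorldMotion)
    marker_noise_sd: float = 0.0                   # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 11:
            raise InputError("n_samples must be >= 11")
        if self.cycle_duration <= 0:
            raise InputError("cycle_duration must be positive")
        if self.flexion_amplitude < 0 or self.out_of_plane_amplitude < 0:
            raise InputError("amplitudes must be >= 0")
        if self.flexion_profile not in ("gait_double_hump", "raised_cosine"):
            raise InputError(f"unknown flexion profile {self.flexion_profile!r}")
        u = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise InputError("axis_direction must be a unit vector")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    flexion_curve: np.ndarray              # deg, per sample
    true_axis_direction: np.ndarray        # femur frame, unit
    true_axis_point: np.ndarray            # femur frame, m
    true_out_of_plane: np.ndarray          # (n, 2) deg


def _raised_cosine(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * x))


def _bump(x: np.ndarray, centre: float, width: float) -> np.ndarray:
    out = np.zeros_like(x)
    inside = np.abs(x - centre) < width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * (x[inside] - centre) / width))
    return out


def flexion_profile(x: np.ndarray, kind: str, amplitude: float) -> np.ndarray:
    """Flexion angle (deg) over the normalised cycle x in [0, 1].

    ``gait_double_hump``: small stance-phase flexion wave near 15% of the
    cycle plus the full swing-phase flexion peak near 70%, rescaled so
    max - min equals ``amplitude``.  ``raised_cosine``: one smooth
    flex-and-return wave (useful as an analytically clean hinge).
    """
    if kind == "raised_cosine":
        return amplitude * _raised_cosine(x)
    raw = 0.18 * _bump(x, 0.15, 0.15) + _bump(x, 0.70, 0.18)
    span = raw.max() - raw.min()
    return amplitude * (raw - raw.min()) / span if span > 0 else np.zeros_like(x)


def _orthonormal_complement(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    b2 = np.cross(u, helper)
    b2 /= np.linalg.norm(b2)
    return b2, np.cross(u, b2)


def simulate_knee(
    config: SimulationConfig | None = None,
) -> tuple[PoseTrajectory, PoseTrajectory, GroundTruth]:
    """Generate femur and tibia world-pose trajectories plus ground truth.

    The relative motion is a rotation of ``flexion_curve(t)`` about the
    configured axis through ``axis_point``, post-composed with small
    out-of-plane sinusoids (1x and 2x the cycle frequency) about the two
    complementary axes; the tibia origin sits at ``tibia_offset`` at rest.
    The femur itself follows a smooth rigid world motion so that neither
    segment is static in the lab.
    """
    cfg = config or SimulationConfig()
    n = cfg.n_samples
    t = np.linspace(0.0, cfg.cycle_duration, n)
    x = t / cfg.cycle_duration

    theta = flexion_profile(x, cfg.flexion_profile, cfg.flexion_amplitude)
    a2 = cfg.out_of_plane_amplitude * np.sin(2.0 * np.pi * x)
    a3 = cfg.out_of_plane_amplitude * np.sin(4.0 * np.pi * x)

    u = np.asarray(cfg.axis_direction, dtype=float)
    c = np.asarray(cfg.axis_point, dtype=float)
    d = np.asarray(cfg.tibia_offset, dtype=float)
    b2, b3 = _orthonormal_complement(u)

    rad = np.pi / 180.0
    R_flex = Rotation.from_rotvec(np.outer(theta * rad, u)).as_matrix()
    R_oop = (
        Rotation.from_rotvec(np.outer(a2 * rad, b2))
        * Rotation.from_rotvec(np.outer(a3 * rad, b3))
    ).as_matrix()
    R_rel = R_flex @ R_oop
    # rotate about the axis through c, then place the tibia origin at d
    p_rel = c - np.einsum("nij,j->ni", R_rel, c) + np.einsum("nij,j->ni", R_rel, d)

    # femur world motion: progression + smooth oscillations
    wm = cfg.femur_world_motion
    p_fm = np.column_stack(
        [
            wm.translation_amplitude * x + 0.02 * np.sin(4.0 * np.pi * x),
            0.90 + 0.03 * np.sin(4.0 * np.pi * x + 1.0),
            0.01 * np.sin(2.0 * np.pi * x),
        ]
    )
    ra = wm.rotation_amplitude * rad
    eul = np.column_stack(
        [
            0.3 * ra * np.sin(2.0 * np.pi * x + 0.5),
            0.5 * ra * np.sin(2.0 * np.pi * x + 1.3),
            ra * np.sin(2.0 * np.pi * x),
        ]
    )
    R_fm = Rotation.from_euler("xyz", eul).as_matrix()

    R_tb = R_fm @ R_rel
    p_tb = np.einsum("nij,nj->ni", R_fm, p_rel) + p_fm

    fm = PoseTrajectory(t, R_fm, p_fm, ("0", "fm"))
    tb = PoseTrajectory(t, R_tb, p_tb, ("0", "tb"))
    truth = GroundTruth(
        flexion_curve=theta,
        true_axis_direction=u,
        true_axis_point=c,
        true_out_of_plane=np.column_stack([a2, a3]),
    )
    return fm, tb, truth


def attach_marker_clusters(
    fm: PoseTrajectory,
    tb: PoseTrajectory,
    cluster_fm: np.ndarray | None = None,
    cluster_tb: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[MarkerTrajectory, MarkerTrajectory]:
    """Rigidly attach marker clusters (segment-frame coordinates) to both
    segments and return their lab-frame trajectories, with optional isotropic
    zero-mean Gaussian noise of ``noise_sd`` metres per coordinate."""
    rng = np.random.default_rng(seed)
    out = []
    for traj, cluster, label in (
        (fm, cluster_fm if cluster_fm is not None else DEFAULT_FEMUR_CLUSTER, "fm"),
        (tb, cluster_tb if cluster_tb is not None else DEFAULT_TIBIA_CLUSTER, "tb"),
    ):
        cluster = np.asarray(cluster, dtype=float)
        pos = np.einsum("nij,mj->nmi", traj.Rs, cluster) + traj.ps[:, None, :]
        if noise_sd > 0.0:
            pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
        ids = [f"{label}{k + 1}" for k in range(cluster.shape[0])]
        out.append(MarkerTrajectory(ids, pos, traj.times.copy(), segment=label))
    return out[0], out[1]
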