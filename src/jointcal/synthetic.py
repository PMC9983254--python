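"""Seeded generator of ground-truthed rig data.

Emulates the physical test stand: a hidden rigid motion links the optical
tracker frame to the robot world frame; commanded calibration poses (a first
group on the robot's YZ plane, a second on its XZ plane) are observed in the
optical frame through the inverse motion plus Gaussian marker noise; the
manual joint motion is a distal marker swept along physiological arcs on a
sphere around the true joint rotation center; gross outliers can be injected
on demand.

Default constants mirror the rig scale (limb-plus-holder length ≈ 367 mm,
joint center ≈ 1 m from the robot origin, 50 mm mounting-grid pitch) so that
synthetic deviation magnitudes are comparable to the validation report.

All randomness flows through :func:`numpy.random.default_rng` (PCG64) with
explicit seeds; every operation derives its stream from the scenario seed
and a fixed stream tag, so regeneration is bit-identical regardless of call
order or platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import CalibrationInputs
from .errors import JointcalError
from .geometry import ARAMIS, ROBOT, FrameTransform, PointSet

# Stream tags for per-operation RNG derivation.
_STREAM_RIG = 11
_STREAM_CAL = 12
_STREAM_ROM = 13
_STREAM_OUTLIER = 14


@dataclass(frozen=True)
class ArcSpec:
    """One physiological movement arc.

    ``kind`` is one of ``flexion_extension`` (rotation about the rig x-axis),
    ``abduction_adduction`` (about the y-axis) or ``circumduction`` (cone
    around the rest limb direction; ``start_deg``/``end_deg`` bound the sweep
    angle and ``cone_deg`` is the half-angle).
    """

    kind: str
    start_deg: float
    end_deg: float
    n: int
    cone_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("flexion_extension", "abduction_adduction", "circumduction"):
            raise JointcalError(f"unknown arc kind {self.kind!r}")
        if self.n < 1:
            raise JointcalError("arc sample count must be >= 1")


#: Conservative default hip range of motion: flexion–extension 0–90°,
#: abduction–adduction 0–45°, circumduction cone of 30° (240 samples total).
DEFAULT_ARCS: tuple[ArcSpec, ...] = (
    ArcSpec("flexion_extension", 0.0, 90.0, 100),
    ArcSpec("abduction_adduction", -22.5, 22.5, 80),
    ArcSpec("circumduction", 0.0, 360.0, 60, cone_deg=15.0),
)

#: Six mounting positions on the 50 mm hole matrix (x/y offsets, z = 0).
DEFAULT_MOUNTING_OFFSETS: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (50.0, 0.0, 0.0),
    (0.0, 50.0, 0.0),
    (50.0, 50.0, 0.0),
    (100.0, 0.0, 0.0),
    (0.0, 100.0, 0.0),
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class SyntheticScenario:
    """Full parameterization of one synthetic rig, reproducible from ``seed``."""

    seed: int = 0
    rotation: np.ndarray | None = None  # ARAMIS -> ROBOT rotation
    translation: np.ndarray | None = None  # ARAMIS -> ROBOT translation
    true_jrc: np.ndarray = field(default_factory=lambda: np.array([1010.0, -125.0, 60.0]))
    true_lot: float = 367.0
    noise_sd: float = 0.1
    n_calibration_poses: int = 11
    rom_arcs: tuple[ArcSpec, ...] = DEFAULT_ARCS
    radii_scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    mounting_offsets: tuple = DEFAULT_MOUNTING_OFFSETS
    grid_pitch: float = 50.0
    outlier_count: int = 0
    outlier_magnitude: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise JointcalError("noise_sd must be non-negative")
        if self.true_lot <= 0:
            raise JointcalError("true_lot must be positive")
        if self.n_calibration_poses < 8:
            raise JointcalError("need at least 8 calibration poses (5 YZ + 3 XZ)")
        if not self.rom_arcs:
            raise JointcalError("rom_arcs must be non-empty")
        rng = np.random.default_rng([self.seed, _STREAM_RIG])
        if self.rotation is None:
            self.rotation = _random_rotation(rng)
        else:
            self.rotation = np.asarray(self.rotation, dtype=float)
        if self.translation is None:
            self.translation = np.array([650.0, -280.0, 140.0]) + rng.uniform(-50, 50, 3)
        else:
            self.translation = np.asarray(self.translation, dtype=float)
        self.true_jrc = np.asarray(self.true_jrc, dtype=float).reshape(3)
        self.radii_scale = np.asarray(self.radii_scale, dtype=float).reshape(3)

    @property
    def true_transform(self) -> FrameTransform:
        """The hidden rigid motion as an optical→robot frame transform."""
        return FrameTransform(
            linear_map=self.rotation,
            source_anchor=np.zeros(3),
            target_anchor=self.translation,
            source_frame=ARAMIS,
            target_frame=ROBOT,
        )

    def robot_to_aramis(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (self.rotation.T @ (pts - self.translation).T).T

    def aramis_to_robot(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (self.rotation @ pts.T).T + self.translation


def _commanded_poses(n_total: int) -> np.ndarray:
    """Commanded pose schedule: 5 poses on the YZ plane (constant x), the
    remaining poses on the XZ plane through the first pose (constant y)."""
    x0, y0 = 700.0, -150.0
    yz = np.array(
        [
            [x0, y0, -100.0],
            [x0, 150.0, -100.0],
            [x0, 150.0, 100.0],
            [x0, -150.0, 100.0],
            [x0, 0.0, 0.0],
        ]
    )
    n_xz = n_total - 5
    if n_xz < 3:
        raise JointcalError("need at least 3 XZ-plane poses")
    # Spread XZ poses on a circle in the plane y = y0 around (x0, y0, 0).
    ang = np.linspace(0.0, 2 * np.pi, n_xz, endpoint=False)
    xz = np.column_stack(
        [x0 + 120.0 * np.cos(ang), np.full(n_xz, y0), 130.0 * np.sin(ang)]
    )
    return np.vstack([yz, xz])


def simulate_calibration_poses(s: SyntheticScenario) -> tuple[PointSet, PointSet]:
    """Paired (commanded robot, observed optical) calibration pose sets.

    The optical observations are the commanded poses pushed through the
    inverse rig motion plus isotropic Gaussian noise of ``s.noise_sd`` mm.
    """
    commanded = _commanded_poses(s.n_calibration_poses)
    rng = np.random.default_rng([s.seed, _STREAM_CAL])
    optical = s.robot_to_aramis(commanded)
    if s.noise_sd > 0:
        optical = optical + rng.normal(0.0, s.noise_sd, optical.shape)
    idx = np.arange(1, len(commanded) + 1)
    return (
        PointSet(frame=ROBOT, points=commanded, pose_indices=idx),
        PointSet(frame=ARAMIS, points=optical, pose_indices=idx.copy()),
    )


def _rot_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _arc_directions(arc: ArcSpec) -> np.ndarray:
    """Unit limb directions for one arc, starting from the rest pose (0,0,−1)."""
    d0 = np.array([0.0, 0.0, -1.0])
    angles = np.deg2rad(np.linspace(arc.start_deg, arc.end_deg, arc.n))
    if arc.kind == "flexion_extension":
        axis = np.array([1.0, 0.0, 0.0])
        return np.stack([_rot_axis(axis, a) @ d0 for a in angles])
    if arc.kind == "abduction_adduction":
        axis = np.array([0.0, 1.0, 0.0])
        return np.stack([_rot_axis(axis, a) @ d0 for a in angles])
    # circumduction: tilt by the cone half-angle, sweep around the rest axis
    tilted = _rot_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(arc.cone_deg)) @ d0
    return np.stack([_rot_axis(d0, a) @ tilted for a in angles])


def simulate_manual_rom(s: SyntheticScenario) -> tuple[PointSet, np.ndarray]:
    """Manual joint motion: noisy optical recording plus robot-frame truth.

    The distal marker sits at distance ``true_lot`` from ``true_jrc`` (per
    axis scaled by ``radii_scale``; unit scale gives an exact sphere) and is
    swept along each configured arc.  Returns the concatenated noisy
    recording in the optical frame and the noiseless robot-frame trajectory.
    """
    dirs = np.vstack([_arc_directions(arc) for arc in s.rom_arcs])
    truth_robot = s.true_jrc + s.true_lot * (dirs * s.radii_scale)
    optical = s.robot_to_aramis(truth_robot)
    rng = np.random.default_rng([s.seed, _STREAM_ROM])
    if s.noise_sd > 0:
        optical = optical + rng.normal(0.0, s.noise_sd, optical.shape)
    return PointSet(frame=ARAMIS, points=optical), truth_robot


def add_outliers(
    points: PointSet,
    count: int,
    magnitude: float,
    seed: int = 0,
) -> PointSet:
    """Displace ``count`` randomly chosen samples by ``magnitude`` mm.

    Directions are uniform on the unit sphere; the affected indices are
    recorded in ``metadata['outlier_indices']``.
    """
    if count < 0:
        raise JointcalError("outlier count must be non-negative")
    if count >= len(points):
        raise JointcalError(f"outlier count {count} must be below sample count {len(points)}")
    if count == 0:
        return replace(points, points=points.points.copy())
    rng = np.random.default_rng([seed, _STREAM_OUTLIER])
    idx = np.sort(rng.choice(len(points), size=count, replace=False))
    dirs = rng.normal(size=(count, 3))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = points.points.copy()
    pts[idx] += magnitude * dirs
    meta = dict(points.metadata)
    meta["outlier_indices"] = [int(i) for i in idx]
    return replace(points, points=pts, metadata=meta)


@dataclass
class SyntheticDataset:
    """Calibration inputs plus the ground truth they were generated from."""

    scenario: SyntheticScenario
    inputs: CalibrationInputs
    true_transform: FrameTransform
    true_jrc: np.ndarray
    true_lot: float
    robot_trajectory_truth: np.ndarray
    aramis_trajectory_clean: np.ndarray


def make_dataset(s: SyntheticScenario) -> SyntheticDataset:
    """Generate one complete, internally consistent synthetic dataset."""
    robot_poses, optical_poses = simulate_calibration_poses(s)
    manual, truth_robot = simulate_manual_rom(s)
    if s.outlier_count > 0:
        manual = add_outliers(manual, s.outlier_count, s.outlier_magnitude, seed=s.seed)
    return SyntheticDataset(
        scenario=s,
        inputs=CalibrationInputs(
            robot_poses=robot_poses,
            optical_poses=optical_poses,
            manual_trajectory=manual,
        ),
        true_transform=s.true_transform,
        true_jrc=s.true_jrc.copy(),
        true_lot=s.true_lot,
        robot_trajectory_truth=truth_robot,
        aramis_trajectory_clean=s.robot_to_aramis(truth_robot),
    )


def sphere_test_points(
    center: Sequence[float],
    radius: float,
    n: int,
    *,
    seed: int = 0,
    noise_sd: float = 0.0,
    hemisphere: bool = False,
) -> np.ndarray:
    """Random points on (or near) a sphere — building block for fit studies.

    With ``hemisphere=True`` the points are restricted to ``z >= center_z``,
    mimicking trajectories that cover only part of the joint surface.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if hemisphere:
        dirs[:, 2] = np.abs(dirs[:, 2])
    pts = np.asarray(center, dtype=float) + radius * dirs
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts
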