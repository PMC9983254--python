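"""Three-stage calibration pipeline.

Stage I records the manual joint motion in the optical frame; stage II drives
the robot through a fixed pose schedule (a first group on its YZ plane, a
second group on its XZ plane) observed in both frames; stage III combines the
two: the optical→robot transform is estimated from the paired poses, the
joint rotation center is fitted as a sphere center in the optical frame and
mapped into robot world coordinates (the tool center point, TCP), and the
tool length (LOT) follows as the distance from the TCP to the flange center.

Two reproduction routes are supported: ``tcp_lot`` (TCP + tool length,
appropriate for ball joints only — gated on the sphericity verdict) and
``trajectory`` (the manual trajectory mapped point-by-point into robot
coordinates, applicable to any joint shape).

The robot-world origin reconstruction used for the accuracy audit intersects
the two fitted calibration planes into a line and compares it against the
line implied by the commanded poses; the plane-intersection algebra is this
package's construction (the published procedure states inputs and output
semantics only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DegenerateGeometryError, FrameMismatchError, JointcalError
from .geometry import (
    ARAMIS,
    ROBOT,
    FrameTransform,
    PointSet,
    apply_transform,
    apply_transform_xyz,
    estimate_transform,
    zero_shift,
)
from . import spherefit as spherefit_defaults
from .spherefit import RobustFitReport, fit_sphere_robust

Method = Literal["tcp_lot", "trajectory"]

#: Default pose-schedule split: first 5 poses on the YZ plane, rest on XZ.
DEFAULT_N_YZ = 5

#: Planes closer to parallel than this |cos| bound cannot be intersected.
_PARALLEL_COS_LIMIT = 0.999


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane ``{p : unit_normal · p = offset}``."""

    unit_normal: np.ndarray
    offset: float
    rms_residual: float
    label: str = ""

    def __post_init__(self) -> None:
        n = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise JointcalError("unit_normal must have unit length")
        object.__setattr__(self, "unit_normal", n)
        if self.rms_residual < 0:
            raise JointcalError("rms_residual must be non-negative")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.unit_normal - self.offset


@dataclass
class CalibrationInputs:
    """The three recordings the pipeline consumes."""

    robot_poses: PointSet
    optical_poses: PointSet
    manual_trajectory: PointSet | None = None

    def __post_init__(self) -> None:
        if self.robot_poses.frame != ROBOT:
            raise FrameMismatchError("robot_poses must be in the ROBOT frame")
        if self.optical_poses.frame != ARAMIS:
            raise FrameMismatchError("optical_poses must be in the ARAMIS frame")
        if len(self.robot_poses) != len(self.optical_poses):
            raise JointcalError(
                "pose count mismatch: robot has "
                f"{len(self.robot_poses)}, optical has {len(self.optical_poses)}"
            )
        ri, oi = self.robot_poses.pose_indices, self.optical_poses.pose_indices
        if ri is not None and oi is not None and not np.array_equal(ri, oi):
            raise JointcalError("robot and optical pose_index sequences differ")
        if self.manual_trajectory is not None and self.manual_trajectory.frame != ARAMIS:
            raise FrameMismatchError("manual_trajectory must be in the ARAMIS frame")


@dataclass
class CalibrationOptions:
    """Tunable knobs of :func:`run_calibration` (defaults follow the rig)."""

    k_sd: float = 1.0
    iterations: int = 4
    sphericity_tol: float = spherefit_defaults.DEFAULT_SPHERICITY_TOL
    sensor_offset: float = 0.0
    flange_center: np.ndarray | None = None
    n_yz: int = DEFAULT_N_YZ
    cond_limit: float = 1e12
    seed: int = 0
    max_combinations: int = 200_000
    override_sphericity: bool = False
    orthogonalize: bool = False


@dataclass
class CalibrationResult:
    transform: FrameTransform
    method: Method
    tcp: np.ndarray | None = None
    lot: float | None = None
    origin_deviation: np.ndarray | None = None
    trajectory_robot: PointSet | None = None
    sphere_report: RobustFitReport | None = None
    plane_fits: dict = field(default_factory=dict)


def fit_plane(points: PointSet | np.ndarray, label: str = "") -> PlaneFit:
    """Orthogonal-distance (total least squares) plane fit.

    The normal is the singular vector of the centred point cloud with the
    smallest singular value; collinear or near-collinear clouds (no unique
    plane) raise :class:`DegenerateGeometryError`.
    """
    pts = points.points if isinstance(points, PointSet) else np.atleast_2d(np.asarray(points, float))
    if len(pts) < 3:
        raise JointcalError(f"plane fit needs at least 3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # s[1] ~ 0 means the cloud has no lateral extent -> collinear.
    scale = max(float(s[0]), np.finfo(float).tiny)
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    offset = float(normal @ centroid)
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(unit_normal=normal, offset=offset, rms_residual=rms, label=label)


def _intersect_planes(a: PlaneFit, b: PlaneFit) -> tuple[np.ndarray, np.ndarray]:
    """Intersection line of two planes as ``(point, unit_direction)``."""
    cosang = abs(float(a.unit_normal @ b.unit_normal))
    if cosang > _PARALLEL_COS_LIMIT:
        raise DegenerateGeometryError("calibration planes are near-parallel")
    direction = np.cross(a.unit_normal, b.unit_normal)
    direction = direction / np.linalg.norm(direction)
    # Minimum-norm point satisfying both plane equations.
    normals = np.vstack([a.unit_normal, b.unit_normal])
    offsets = np.array([a.offset, b.offset])
    point, *_ = np.linalg.lstsq(normals, offsets, rcond=None)
    return point, direction


def _closest_point_on_line(point: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    return origin + direction * ((point - origin) @ direction)


def reconstruct_origin(
    yz: PlaneFit,
    xz: PlaneFit,
    commanded: PointSet,
    measured: PointSet,
    t: FrameTransform,
    *,
    n_yz: int = DEFAULT_N_YZ,
) -> np.ndarray:
    """Per-axis deviation of the reconstructed robot-world origin.

    ``yz`` and ``xz`` are planes fitted (in robot world coordinates) to the
    transform-mapped optical observations of the two pose groups.  Their
    intersection is the reconstructed vertical axis.  The same construction
    applied to the commanded poses yields the ideal axis; the commanded
    origin is pinned as the ideal axis's closest point to the robot-world
    origin, and the returned vector is the offset between that pin projected
    onto the reconstructed axis (plus its perpendicular miss) and its ideal
    location — identically ``(0, 0, 0)`` for perfect data.
    """
    if t.target_frame != ROBOT:
        raise FrameMismatchError("transform must map into the ROBOT frame")
    if len(commanded) != len(measured):
        raise JointcalError("commanded and measured pose counts differ")
    if not 3 <= n_yz <= len(commanded) - 3:
        raise JointcalError("pose split leaves a plane group with fewer than 3 poses")

    line_pt, line_dir = _intersect_planes(yz, xz)
    ideal_yz = fit_plane(commanded.points[:n_yz], label="YZ")
    ideal_xz = fit_plane(commanded.points[n_yz:], label="XZ")
    ideal_pt, ideal_dir = _intersect_planes(ideal_yz, ideal_xz)

    origin = np.zeros(3)
    pin = _closest_point_on_line(origin, ideal_pt, ideal_dir)
    reconstructed = _closest_point_on_line(pin, line_pt, line_dir)
    return reconstructed - pin


def compute_tcp(
    report: RobustFitReport,
    t: FrameTransform,
    *,
    override_sphericity: bool = False,
) -> np.ndarray:
    """Tool center point: the fitted joint center mapped into robot world.

    Requires a sphere-like verdict from the robust fit unless explicitly
    overridden; non-spherical joints should use the trajectory route.
    """
    if not report.spherical and not override_sphericity:
        raise JointcalError("trajectory not sphere-like; use trajectory method")
    if t.target_frame != ROBOT:
        raise FrameMismatchError("transform must map into the ROBOT frame")
    return apply_transform_xyz(t, report.final.center)


def compute_lot(
    tcp: np.ndarray,
    flange_center: np.ndarray,
    sensor_offset: float = 0.0,
) -> float:
    """Length of tool: TCP-to-flange distance minus any sensor stack length.

    Both points must be expressed in robot world coordinates.
    """
    lot = float(np.linalg.norm(np.asarray(tcp, float) - np.asarray(flange_center, float)))
    lot -= sensor_offset
    if lot <= 0:
        raise JointcalError("sensor offset exceeds distance")
    return lot


def transform_trajectory(manual: PointSet, t: FrameTransform) -> PointSet:
    """Map a manually recorded trajectory into robot world coordinates.

    No sphericity requirement: this route works for any joint shape.
    Ordering and sample count are preserved.
    """
    if manual.frame != t.source_frame:
        raise FrameMismatchError(
            f"trajectory is in frame {manual.frame!r}, transform expects {t.source_frame!r}"
        )
    return apply_transform(t, manual)


def project_to_sphere(points: PointSet | np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially project points onto a sphere (TCP/LOT motion reproduction)."""
    pts = points.points if isinstance(points, PointSet) else np.atleast_2d(np.asarray(points, float))
    center = np.asarray(center, float).reshape(3)
    rel = pts - center
    norms = np.linalg.norm(rel, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateGeometryError("point coincides with sphere center")
    return center + rel / norms * radius


def _stage(name: str):
    """Context decorator that prefixes stage names onto raised errors."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, JointcalError):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_calibration(
    inputs: CalibrationInputs,
    method: Method = "tcp_lot",
    options: CalibrationOptions | None = None,
) -> CalibrationResult:
    """Run the full pipeline and assemble a :class:`CalibrationResult`.

    Composes zero-shift → transform estimation → origin reconstruction, then
    per ``method`` either the robust sphere fit → TCP → LOT chain or the
    plain trajectory transformation (the trajectory is mapped in both cases
    when present).  Deterministic for fixed inputs and options.
    """
    opts = options or CalibrationOptions()
    if method not in ("tcp_lot", "trajectory"):
        raise JointcalError(f"unknown method {method!r}")
    if inputs.manual_trajectory is None:
        raise JointcalError(f"method {method!r} requires the manual_trajectory input")

    with _stage("transform"):
        robot_zeroed = zero_shift(inputs.robot_poses)
        optical_zeroed = zero_shift(inputs.optical_poses)
        transform = estimate_transform(
            robot_zeroed,
            optical_zeroed,
            cond_limit=opts.cond_limit,
            orthogonalize=opts.orthogonalize,
        )

    result = CalibrationResult(transform=transform, method=method)

    n = len(inputs.robot_poses)
    if 3 <= opts.n_yz <= n - 3:
        with _stage("origin"):
            mapped = apply_transform(transform, inputs.optical_poses)
            yz = fit_plane(mapped.points[: opts.n_yz], label="YZ")
            xz = fit_plane(mapped.points[opts.n_yz :], label="XZ")
            result.plane_fits = {"YZ": yz, "XZ": xz}
            result.origin_deviation = reconstruct_origin(
                yz, xz, inputs.robot_poses, inputs.optical_poses, transform, n_yz=opts.n_yz
            )

    with _stage("trajectory"):
        result.trajectory_robot = transform_trajectory(inputs.manual_trajectory, transform)

    if method == "tcp_lot":
        with _stage("spherefit"):
            result.sphere_report = fit_sphere_robust(
                inputs.manual_trajectory,
                k_sd=opts.k_sd,
                iterations=opts.iterations,
                sphericity_tol=opts.sphericity_tol,
                max_combinations=opts.max_combinations,
                seed=opts.seed,
            )
        with _stage("tcp"):
            result.tcp = compute_tcp(
                result.sphere_report, transform, override_sphericity=opts.override_sphericity
            )
        with _stage("lot"):
            if opts.flange_center is not None:
                result.lot = compute_lot(result.tcp, opts.flange_center, opts.sensor_offset)
            else:
                # Without a flange pose the tracked marker is the most distal
                # reference: the fitted radius is the TCP-to-marker distance.
                lot = float(result.sphere_report.final.radius) - opts.sensor_offset
                if lot <= 0:
                    raise JointcalError("sensor offset exceeds distance")
                result.lot = lot
    return result
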