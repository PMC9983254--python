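"""Coordinate-frame data model and optical→robot transformation estimation.

The rig relates two Cartesian frames: the optical tracker frame (``ARAMIS``)
and the robot world frame (``ROBOT``).  Paired calibration poses recorded in
both frames are first shifted so the first pose becomes the common zero point;
the residual linear relation between the zeroed point clouds is then estimated
by an unconstrained least-squares solve of ``R = T · A`` via the normal
equations, ``T = R · Aᵀ · (A · Aᵀ)⁻¹``.  No orthogonality constraint is
imposed on the estimate (an optional post-hoc orthogonalization is available
for users who want a strictly rigid map).

All lengths are millimetres, frames are right-handed, pose indices are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, FrameMismatchError, JointcalError

#: Canonical frame labels.
ARAMIS = "ARAMIS"
ROBOT = "ROBOT"

#: Conditioning guard for the 3×3 normal matrix (and other solves).
DEFAULT_COND_LIMIT = 1e12

#: Minimum pose count for transformation estimation.
DEFAULT_MIN_POSES = 4


@dataclass(frozen=True)
class MarkerSample:
    """One tracked marker observation in a named frame.

    Orientation angles, when present, are carried through I/O as metadata
    only; the transformation equations use positions exclusively.
    """

    frame: str
    pose_index: int
    position: np.ndarray
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise JointcalError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise JointcalError("position components must be finite")
        if self.pose_index < 1:
            raise JointcalError("pose_index must be >= 1")
        object.__setattr__(self, "position", pos)
        if self.orientation is not None:
            ori = np.asarray(self.orientation, dtype=float)
            if ori.shape != (3,):
                raise JointcalError("orientation must be a 3-vector of angles")
            object.__setattr__(self, "orientation", ori)


@dataclass
class PointSet:
    """An ordered set of 3D positions expressed in one named frame.

    Parameters
    ----------
    frame
        Frame label, typically :data:`ARAMIS` or :data:`ROBOT`.
    points
        ``(n, 3)`` array of positions in mm.
    zeroed
        Whether the set has been shifted so its first point is the origin.
    anchor
        The point subtracted during zeroing (recorded iff ``zeroed``).
    pose_indices
        Optional 1-based pose indices, unique within the set.
    orientations
        Optional ``(n, 3)`` rotation angles in degrees (metadata only).
    """

    frame: str
    points: np.ndarray
    zeroed: bool = False
    anchor: np.ndarray | None = None
    pose_indices: np.ndarray | None = None
    orientations: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise JointcalError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise JointcalError("no samples")
        if not np.all(np.isfinite(pts)):
            raise JointcalError("point coordinates must be finite")
        self.points = pts
        if self.zeroed:
            if self.anchor is None:
                raise JointcalError("zeroed PointSet must record its anchor")
            if not np.allclose(pts[0], 0.0):
                raise JointcalError("zeroed PointSet must start at the origin")
            self.anchor = np.asarray(self.anchor, dtype=float)
        elif self.anchor is not None:
            raise JointcalError("anchor is recorded iff the set is zeroed")
        if self.pose_indices is not None:
            idx = np.asarray(self.pose_indices, dtype=int)
            if idx.shape != (len(pts),):
                raise JointcalError("pose_indices length mismatch")
            if len(np.unique(idx)) != len(idx):
                raise JointcalError("pose_index must be unique within a recording")
            self.pose_indices = idx
        if self.orientations is not None:
            ori = np.asarray(self.orientations, dtype=float)
            if ori.shape != pts.shape:
                raise JointcalError("orientations must match points in shape")
            self.orientations = ori

    @classmethod
    def from_samples(cls, samples: Iterable[MarkerSample]) -> "PointSet":
        samples = list(samples)
        if not samples:
            raise JointcalError("no samples")
        frames = {s.frame for s in samples}
        if len(frames) != 1:
            raise FrameMismatchError(f"mixed frames in recording: {sorted(frames)}")
        ori = None
        if all(s.orientation is not None for s in samples):
            ori = np.vstack([s.orientation for s in samples])
        return cls(
            frame=samples[0].frame,
            points=np.vstack([s.position for s in samples]),
            pose_indices=np.array([s.pose_index for s in samples]),
            orientations=ori,
        )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class FrameTransform:
    """Estimated linear map plus translation anchors linking two frames.

    Maps a point ``p`` in the source frame to
    ``target_anchor + linear_map · (p − source_anchor)``.
    """

    linear_map: np.ndarray
    source_anchor: np.ndarray
    target_anchor: np.ndarray
    source_frame: str
    target_frame: str
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.linear_map, dtype=float)
        if m.shape != (3, 3):
            raise JointcalError("linear_map must be 3x3")
        if not np.all(np.isfinite(m)):
            raise JointcalError("linear_map must be finite")
        self.linear_map = m
        self.source_anchor = np.asarray(self.source_anchor, dtype=float).reshape(3)
        self.target_anchor = np.asarray(self.target_anchor, dtype=float).reshape(3)

    @property
    def direction(self) -> str:
        return f"{self.source_frame}->{self.target_frame}"

    def orthogonality_error(self) -> float:
        """Max-norm departure of the linear map from orthogonality."""
        m = self.linear_map
        return float(np.max(np.abs(m.T @ m - np.eye(3))))


def zero_shift(points: PointSet) -> PointSet:
    """Shift all coordinates so the first sample becomes the zero point.

    The first sample is recorded as the set's anchor; subsequent operations
    that compose transforms use it to restore absolute positions.
    """
    if points.zeroed:
        raise JointcalError("point set is already zeroed")
    anchor = points.points[0].copy()
    return replace(
        points,
        points=points.points - anchor,
        zeroed=True,
        anchor=anchor,
    )


def estimate_transform(
    target: PointSet,
    source: PointSet,
    *,
    cond_limit: float = DEFAULT_COND_LIMIT,
    min_poses: int = DEFAULT_MIN_POSES,
    orthogonalize: bool = False,
) -> FrameTransform:
    """Least-squares estimate of the linear map from ``source`` to ``target``.

    Both point sets must be zeroed and in pose correspondence.  With the
    zeroed 3×n data matrices ``A`` (source) and ``R`` (target), the map is

        ``T = R · Aᵀ · (A · Aᵀ)⁻¹``

    which is the unconstrained least-squares solution of ``R = T · A``.

    Parameters
    ----------
    target, source
        Zeroed point sets with equal length ``n >= min_poses``.
    cond_limit
        Maximum allowed condition number of ``A · Aᵀ``.
    orthogonalize
        If true, replace the estimate with its nearest orthogonal matrix
        (polar factor).  Off by default: the published estimator is
        unconstrained.

    Raises
    ------
    DegenerateGeometryError
        If the source geometry is (near-)coplanar through the origin, i.e.
        ``A · Aᵀ`` is ill-conditioned.
    """
    if not (target.zeroed and source.zeroed):
        raise JointcalError("both point sets must be zeroed before estimation")
    if len(target) != len(source):
        raise JointcalError(
            f"pose count mismatch: target has {len(target)}, source has {len(source)}"
        )
    if len(source) < min_poses:
        raise JointcalError(f"need at least {min_poses} poses, got {len(source)}")

    a = source.points.T  # (3, n)
    r = target.points.T
    normal = a @ a.T
    if np.linalg.cond(normal) > cond_limit:
        raise DegenerateGeometryError("degenerate calibration geometry")
    linear_map = r @ a.T @ np.linalg.inv(normal)
    if orthogonalize:
        u, _, vt = np.linalg.svd(linear_map)
        linear_map = u @ vt
    residual = r - linear_map @ a
    residual_rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=0))))
    return FrameTransform(
        linear_map=linear_map,
        source_anchor=source.anchor,
        target_anchor=target.anchor,
        source_frame=source.frame,
        target_frame=target.frame,
        residual_rms=residual_rms,
    )


def invert_transform(t: FrameTransform, *, cond_limit: float = DEFAULT_COND_LIMIT) -> FrameTransform:
    """Inverse transform: direction reversed, anchors swapped."""
    if np.linalg.cond(t.linear_map) > cond_limit:
        raise DegenerateGeometryError("linear map is singular; cannot invert")
    return FrameTransform(
        linear_map=np.linalg.inv(t.linear_map),
        source_anchor=t.target_anchor,
        target_anchor=t.source_anchor,
        source_frame=t.target_frame,
        target_frame=t.source_frame,
        residual_rms=t.residual_rms,
    )


def apply_transform(t: FrameTransform, points: PointSet) -> PointSet:
    """Map every point into the transform's target frame.

    Zeroing state is not carried over: the output is an absolute point set in
    the target frame.
    """
    if points.frame != t.source_frame:
        raise FrameMismatchError(
            f"points are in frame {points.frame!r}, transform expects {t.source_frame!r}"
        )
    pts = points.points
    if points.zeroed and points.anchor is not None:
        pts = pts + points.anchor
    mapped = (t.linear_map @ (pts - t.source_anchor).T).T + t.target_anchor
    return PointSet(
        frame=t.target_frame,
        points=mapped,
        pose_indices=None if points.pose_indices is None else points.pose_indices.copy(),
        orientations=None if points.orientations is None else points.orientations.copy(),
    )


def apply_transform_xyz(t: FrameTransform, xyz: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map a bare 3-vector (source frame) through the transform."""
    p = np.asarray(xyz, dtype=float).reshape(3)
    return t.target_anchor + t.linear_map @ (p - t.source_anchor)
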