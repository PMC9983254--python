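"""Sphere fitting of joint trajectories.

A ball-and-socket joint constrains a distal marker to (approximately) a
sphere around the joint rotation center.  Writing the sphere equation

    ``(x − x_m)² + (y − y_m)² + (z − z_m)² = R²``

in the linearized form ``p₁ + p₂·x + p₃·y + p₄·z = −(x² + y² + z²)`` with

    ``p₁ = x_m² + y_m² + z_m² − R²``,  ``p₂ = −2·x_m``,
    ``p₃ = −2·y_m``,  ``p₄ = −2·z_m``

turns the fit into a linear solve.  Three estimators are provided:

* :func:`fit_sphere_linear` — one least-squares solve over all samples via
  the normal equations (fast, but sensitive to gross outliers and
  ill-conditioning);
* :func:`fit_sphere_4pt` — exact solve through four points;
* :func:`fit_sphere_robust` — solves every four-point combination of the
  samples, then iteratively discards ensemble members whose parameters fall
  outside a ``k·SD`` band around the ensemble mean, and averages the
  survivors.  The spread of the surviving parameters doubles as a sphericity
  verdict for the trajectory.

Standard deviations are population SDs (divisor ``n``) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations as _iter_combinations
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, JointcalError
from .geometry import PointSet

#: Above this many four-point combinations the ensemble is subsampled.
DEFAULT_MAX_COMBINATIONS = 200_000

#: Default sphericity verdict tolerance (mm) on the surviving parameter SDs.
#: Four-point solves amplify marker noise, so even a true sphere recorded at
#: ~0.2 mm noise shows an ensemble SD of a few mm; strongly aspherical
#: trajectories exceed this by an order of magnitude.  Callers with tighter
#: test tolerances should pass their own value.
DEFAULT_SPHERICITY_TOL = 5.0

#: Relative determinant threshold for flagging a quadruple as degenerate.
_DET_RTOL = 1e-12


@dataclass(frozen=True)
class SphereParams:
    """Center ``(x_m, y_m, z_m)`` and radius ``R`` of a fitted sphere, in mm."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise JointcalError("sphere radius must be positive and finite")

    @property
    def p_vector(self) -> np.ndarray:
        """The linearized parameter vector ``(p₁, p₂, p₃, p₄)``."""
        x, y, z = self.center
        p1 = x * x + y * y + z * z - self.radius**2
        return np.array([p1, -2 * x, -2 * y, -2 * z])

    def residuals(self, points: np.ndarray) -> np.ndarray:
        """Signed radial residuals ``‖p − center‖ − R`` per point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(pts - self.center, axis=1) - self.radius


@dataclass(frozen=True)
class FourPointFit:
    """Exact sphere solve through one quadruple of measurement indices."""

    combination: tuple[int, int, int, int]
    p: np.ndarray | None
    sphere: SphereParams | None
    valid: bool


@dataclass
class RobustFitReport:
    """Outcome of the combinatorial fit with iterative threshold rejection.

    ``params`` holds one row ``(x_m, y_m, z_m, R)`` per attempted quadruple
    (NaN where the quadruple was degenerate).  ``survivor_mask_per_iteration``
    starts with the initial validity mask and appends the mask after each
    applied rejection pass; survivor counts never increase.
    """

    combinations: np.ndarray
    params: np.ndarray
    valid: np.ndarray
    survivor_mask_per_iteration: list[np.ndarray]
    iterations_run: int
    final: SphereParams
    param_sd: np.ndarray
    spherical: bool
    tolerance_used: float
    k_sd: float
    subsampled: bool = False

    @property
    def survivors(self) -> np.ndarray:
        return self.survivor_mask_per_iteration[-1]

    @property
    def all_fits(self) -> list[FourPointFit]:
        """Materialize per-combination fit objects (built lazily; the arrays
        are the primary storage)."""
        fits = []
        for combo, row, ok in zip(self.combinations, self.params, self.valid):
            if ok:
                sphere = SphereParams(center=row[:3], radius=float(row[3]))
                fits.append(FourPointFit(tuple(int(i) for i in combo), sphere.p_vector, sphere, True))
            else:
                fits.append(FourPointFit(tuple(int(i) for i in combo), None, None, False))
        return fits

    def to_dict(self) -> dict:
        surv = self.survivors
        return {
            "n_combinations": int(len(self.combinations)),
            "n_valid": int(self.valid.sum()),
            "n_survivors": int(surv.sum()),
            "iterations_run": self.iterations_run,
            "k_sd": self.k_sd,
            "subsampled": self.subsampled,
            "center_mm": [float(v) for v in self.final.center],
            "radius_mm": float(self.final.radius),
            "param_sd": [float(v) for v in self.param_sd],
            "spherical": bool(self.spherical),
            "tolerance_used_mm": float(self.tolerance_used),
            "survivor_counts": [int(m.sum()) for m in self.survivor_mask_per_iteration],
            "survivor_combinations": [
                [int(i) for i in c] for c in self.combinations[surv]
            ],
        }


def _as_points(points: PointSet | np.ndarray) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.points
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise JointcalError(f"points must have shape (n, 3), got {pts.shape}")
    return pts


def _back_substitute(p: np.ndarray) -> SphereParams:
    center = -p[1:] / 2.0
    r2 = float(np.dot(center, center) - p[0])
    if r2 <= 0:
        raise DegenerateGeometryError("fitted radius squared is non-positive")
    return SphereParams(center=center, radius=math.sqrt(r2))


def fit_sphere_linear(
    points: PointSet | np.ndarray, *, cond_limit: float = 1e12
) -> SphereParams:
    """Single algebraic least-squares sphere fit over all samples.

    Builds the ``n×4`` design with rows ``(1, x, y, z)`` and right side
    ``−(x² + y² + z²)`` and solves the normal equations.

    Raises
    ------
    JointcalError
        If fewer than 4 points are given.
    DegenerateGeometryError
        If the normal matrix is singular or ill-conditioned (e.g. points on
        a planar circle) or the solution has non-positive radius squared.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 4:
        raise JointcalError(f"sphere fit needs at least 4 points, got {n}")
    k = np.column_stack([np.ones(n), pts])
    rhs = -np.sum(pts**2, axis=1)
    ktk = k.T @ k
    if np.linalg.cond(ktk) > cond_limit:
        raise DegenerateGeometryError("degenerate geometry")
    p = np.linalg.solve(ktk, k.T @ rhs)
    return _back_substitute(p)


def enumerate_4pt_combinations(n: int) -> list[tuple[int, int, int, int]]:
    """All ``C(n, 4)`` index quadruples in lexicographic order (0-based)."""
    if n < 4:
        raise JointcalError(f"need at least 4 measurements, got {n}")
    return list(_iter_combinations(range(n), 4))


def _solve_quadruples(pts: np.ndarray, combos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched exact sphere solves.

    Returns ``(params, valid)`` where ``params`` is ``(m, 4)`` rows of
    ``(x_m, y_m, z_m, R)`` (NaN rows where invalid) and ``valid`` marks
    quadruples whose 4×4 system was well-posed with ``R² > 0``.
    """
    m = len(combos)
    quad = pts[combos]  # (m, 4, 3)
    design = np.concatenate([np.ones((m, 4, 1)), quad], axis=2)
    rhs = -np.sum(quad**2, axis=2)
    det = np.linalg.det(design)
    hadamard = np.prod(np.linalg.norm(design, axis=2), axis=1)
    solvable = np.abs(det) > _DET_RTOL * np.maximum(hadamard, np.finfo(float).tiny)

    p = np.full((m, 4), np.nan)
    if solvable.any():
        sol = np.linalg.solve(design[solvable], rhs[solvable][..., None])[..., 0]
        p[solvable] = sol
    centers = -p[:, 1:] / 2.0
    r2 = np.sum(centers**2, axis=1) - p[:, 0]
    with np.errstate(invalid="ignore"):
        valid = solvable & np.all(np.isfinite(p), axis=1) & (r2 > 0)
    radius = np.where(valid, np.sqrt(np.where(r2 > 0, r2, np.nan)), np.nan)
    params = np.column_stack([centers, radius])
    params[~valid] = np.nan
    return params, valid


def fit_sphere_4pt(points: PointSet | np.ndarray | Sequence) -> FourPointFit:
    """Exact sphere through four points.

    Degenerate quadruples (coplanar points, duplicate points, or solutions
    with ``R² <= 0``) are reported with ``valid=False`` rather than raised,
    so combination sweeps never abort.
    """
    pts = _as_points(points)
    if len(pts) != 4:
        raise JointcalError(f"exactly 4 points required, got {len(pts)}")
    params, valid = _solve_quadruples(pts, np.arange(4)[None, :])
    if not valid[0]:
        return FourPointFit((0, 1, 2, 3), None, None, False)
    sphere = SphereParams(center=params[0, :3], radius=float(params[0, 3]))
    return FourPointFit((0, 1, 2, 3), sphere.p_vector, sphere, True)


def _sample_combinations(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform seeded subsample of 4-point combinations (deterministic).

    Draws index quadruples with replacement, keeps rows with four distinct
    members, sorts and deduplicates; the tiny duplicate deficit is accepted
    in exchange for a fully vectorized draw.
    """
    draw = rng.integers(0, n, size=(int(size * 1.3) + 16, 4))
    distinct = (
        (draw[:, 0] != draw[:, 1])
        & (draw[:, 0] != draw[:, 2])
        & (draw[:, 0] != draw[:, 3])
        & (draw[:, 1] != draw[:, 2])
        & (draw[:, 1] != draw[:, 3])
        & (draw[:, 2] != draw[:, 3])
    )
    rows = np.sort(draw[distinct], axis=1)
    rows = np.unique(rows, axis=0)
    if len(rows) > size:
        keep = rng.choice(len(rows), size=size, replace=False)
        rows = rows[np.sort(keep)]
    return rows


def fit_sphere_robust(
    points: PointSet | np.ndarray,
    k_sd: float = 1.0,
    iterations: int = 4,
    *,
    sphericity_tol: float = DEFAULT_SPHERICITY_TOL,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
    seed: int = 0,
    min_survivors: int = 2,
) -> RobustFitReport:
    """Combinatorial sphere fit with iterative SD-threshold rejection.

    Every four-point combination of the samples is solved exactly.  Then, up
    to ``iterations`` times: the mean and population SD of each of
    ``x_m, y_m, z_m, R`` are computed over the current survivors, and every
    fit for which ANY parameter deviates more than ``k_sd·SD`` from its mean
    is removed.  Iteration stops early when the survivor set stabilizes or a
    pass would leave fewer than ``min_survivors``.  The final parameters are
    the arithmetic mean of the survivors; their population SDs measure how
    sphere-like the trajectory is.

    When ``C(n, 4)`` exceeds ``max_combinations`` the ensemble is a uniform
    seeded subsample of that size (deterministic for a given ``seed``).

    Raises
    ------
    JointcalError
        If ``n < 5``, the parameters are out of range, or no quadruple is
        solvable.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 5:
        raise JointcalError(f"robust fit needs at least 5 points, got {n}")
    if k_sd <= 0:
        raise JointcalError("k_sd must be positive")
    if iterations < 1:
        raise JointcalError("iterations must be >= 1")

    total = math.comb(n, 4)
    subsampled = total > max_combinations
    if subsampled:
        rng = np.random.default_rng(seed)
        combos = _sample_combinations(n, max_combinations, rng)
    else:
        combos = np.array(enumerate_4pt_combinations(n), dtype=int)

    params, valid = _solve_quadruples(pts, combos)
    if not valid.any():
        raise JointcalError("no solvable quadruples")

    masks = [valid.copy()]
    iterations_run = 0
    for _ in range(iterations):
        cur = masks[-1]
        sub = params[cur]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0)  # population SD
        keep = cur & np.all(np.abs(params - mean) <= k_sd * sd, axis=1)
        if keep.sum() < min_survivors:
            break
        if np.array_equal(keep, cur):
            break
        masks.append(keep)
        iterations_run += 1

    surv = params[masks[-1]]
    mean = surv.mean(axis=0)
    param_sd = surv.std(axis=0)
    final = SphereParams(center=mean[:3], radius=float(mean[3]))
    return RobustFitReport(
        combinations=combos,
        params=params,
        valid=valid,
        survivor_mask_per_iteration=masks,
        iterations_run=iterations_run,
        final=final,
        param_sd=param_sd,
        spherical=bool(np.max(param_sd) <= sphericity_tol),
        tolerance_used=float(sphericity_tol),
        k_sd=float(k_sd),
        subsampled=subsampled,
    )


def assess_sphericity(report: RobustFitReport, tol: float) -> bool:
    """True iff the largest surviving parameter SD is within ``tol`` mm."""
    return bool(np.max(report.param_sd) <= tol)
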