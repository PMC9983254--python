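"""Summary-statistic conventions and trajectory-reproduction accuracy.

The validation report of the rig uses a fixed set of conventions:

* standard deviations are population SDs (divisor ``n``);
* the "median deviation" is the median of the values minus their mean, with
  the even-``n`` median taken as the mean of the two middle order
  statistics;
* "max deviation '+'" is the largest deviation above the mean and
  "min deviation '−'" the magnitude of the largest deviation below it
  (plain extremes are reported alongside, since some report tables print
  those instead);
* mounting-grid normalization subtracts known hole-matrix offsets so that
  repeated mounts are comparable;
* trajectory reproduction accuracy is evaluated per axis as signed
  deviations plus the per-point Euclidean distance, each summarized by
  average / max / min.

Rounding to table precision is a rendering concern only (:func:`round_half_up`);
all computation is done at full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import JointcalError
from .geometry import PointSet

Pairing = Literal["arclength", "nearest"]


@dataclass(frozen=True)
class SummaryStats:
    """Summary of one report column."""

    mean: float
    sd: float
    median_deviation: float
    max_dev_pos: float
    min_dev_neg: float
    max_value: float
    min_value: float
    n: int


@dataclass(frozen=True)
class TrajectoryComparison:
    """Pointwise deviations between a reference and a test trajectory."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    euclidean: np.ndarray
    summary: dict

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.dx)),
            "summary": self.summary,
        }


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up, used only when rendering report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(values: Sequence[float], *, sd_divisor: Literal["n", "n-1"] = "n") -> SummaryStats:
    """Column summary using the report conventions (population SD default)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 1:
        raise JointcalError("summarize needs a non-empty 1-D sequence")
    mean = float(v.mean())
    ddof = 0 if sd_divisor == "n" else 1
    if ddof == 1 and len(v) < 2:
        raise JointcalError("sample SD needs at least 2 values")
    dev = v - mean
    return SummaryStats(
        mean=mean,
        sd=float(v.std(ddof=ddof)),
        median_deviation=float(np.median(dev)),
        max_dev_pos=float(v.max() - mean),
        min_dev_neg=float(mean - v.min()),
        max_value=float(v.max()),
        min_value=float(v.min()),
        n=len(v),
    )


def center_deviations(values: Sequence[float]) -> np.ndarray:
    """Shift values so their mean deviation is zero."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 1:
        raise JointcalError("center_deviations needs a non-empty 1-D sequence")
    return v - v.mean()


def normalize_positions(
    raw: Sequence[Sequence[float]] | np.ndarray,
    grid_offsets: Sequence[Sequence[float]] | np.ndarray,
    *,
    pitch: float = 50.0,
) -> np.ndarray:
    """Refer repeated-mount positions back to the reference mount.

    Subtracts the known mounting-plate offsets (multiples of the hole-matrix
    ``pitch`` in x/y, zero in z) from each raw position.  Off-grid offsets
    are tolerated with a warning — the measurement may still be useful even
    if the mount bookkeeping is suspect.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    off = np.atleast_2d(np.asarray(grid_offsets, dtype=float))
    if raw.shape != off.shape or raw.shape[1] != 3:
        raise JointcalError("raw and grid_offsets must both have shape (n, 3)")
    remainder = np.abs(off[:, :2] / pitch - np.round(off[:, :2] / pitch))
    if np.any(remainder > 1e-6 / pitch) or np.any(np.abs(off[:, 2]) > 1e-6):
        warnings.warn(
            f"grid offsets are not multiples of the {pitch} mm pitch", stacklevel=2
        )
    return raw - off


def resample_arclength(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a polyline at uniform arc-length fractions."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise JointcalError("resampling needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n_out, axis=0)
    s = s / s[-1]
    u = np.linspace(0.0, 1.0, n_out)
    return np.column_stack([np.interp(u, s, pts[:, k]) for k in range(3)])


def compare_trajectories(
    reference: PointSet | np.ndarray,
    test: PointSet | np.ndarray,
    *,
    pairing: Pairing = "arclength",
) -> TrajectoryComparison:
    """Signed per-axis deviations ``test − reference`` plus Euclidean norms.

    ``arclength`` pairing (default) resamples both curves at uniform
    arc-length fractions to a common count — manual and robotic recordings
    generally have different sample counts — and pairs by index.  ``nearest``
    pairs each test point with its nearest reference point.
    """
    ref = reference.points if isinstance(reference, PointSet) else np.atleast_2d(np.asarray(reference, float))
    tst = test.points if isinstance(test, PointSet) else np.atleast_2d(np.asarray(test, float))
    if isinstance(reference, PointSet) and isinstance(test, PointSet):
        if reference.frame != test.frame:
            raise JointcalError(
                f"trajectories are in different frames: {reference.frame!r} vs {test.frame!r}"
            )
    if len(ref) < 2 or len(tst) < 2:
        raise JointcalError("trajectory comparison needs at least 2 points per curve")

    if pairing == "arclength":
        n_out = max(len(ref), len(tst))
        ref_p = resample_arclength(ref, n_out)
        tst_p = resample_arclength(tst, n_out)
    elif pairing == "nearest":
        tree = cKDTree(ref)
        _, idx = tree.query(tst)
        ref_p = ref[idx]
        tst_p = tst
    else:
        raise JointcalError(f"unknown pairing {pairing!r}")

    delta = tst_p - ref_p
    euclid = np.linalg.norm(delta, axis=1)
    cols = {"dX": delta[:, 0], "dY": delta[:, 1], "dZ": delta[:, 2], "euclidean": euclid}
    summary = {
        name: {
            "average": float(col.mean()),
            "max": float(col.max()),
            "min": float(col.min()),
        }
        for name, col in cols.items()
    }
    return TrajectoryComparison(
        dx=delta[:, 0], dy=delta[:, 1], dz=delta[:, 2], euclidean=euclid, summary=summary
    )
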