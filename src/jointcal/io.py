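"""CSV/JSON readers and writers plus run configuration.

The marker CSV schema is fixed: ``frame,pose_index,x_mm,y_mm,z_mm`` with
optional ``alpha_deg,beta_deg,gamma_deg`` columns, a header row, and dot
decimals.  Tracker exports using other dialects (comma decimals, different
headers) must be converted first; malformed cells are reported with their
file location.  Structured results are JSON at full precision — rounding to
table precision happens only in human-readable rendering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .errors import JointcalError
from .geometry import FrameTransform, PointSet

REQUIRED_COLUMNS = ["frame", "pose_index", "x_mm", "y_mm", "z_mm"]
ORIENTATION_COLUMNS = ["alpha_deg", "beta_deg", "gamma_deg"]


@dataclass
class RunConfig:
    """Shared run configuration with the package-wide defaults."""

    k_sd: float = 1.0
    iterations: int = 4
    sd_divisor: Literal["n", "n-1"] = "n"
    pairing: Literal["arclength", "nearest"] = "arclength"
    sensor_offset: float = 0.0
    grid_pitch: float = 50.0
    cond_limit: float = 1e12
    seed: int = 0
    verbosity: int = 0


def _parse_numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any() or df[column].isna().any():
        row = int(np.flatnonzero(bad | df[column].isna())[0])
        cell = df[column].iloc[row]
        # +2: header line plus 1-based counting.
        raise JointcalError(
            f"{path}:{row + 2}: non-numeric value {cell!r} in column {column!r}"
            " (note: decimal commas are not accepted)"
        )
    return values.to_numpy(dtype=float)


def read_trajectory_csv(path: str | Path, expected_frame: str | None = None) -> PointSet:
    """Read a marker CSV into a :class:`PointSet`.

    Raises :class:`JointcalError` naming the offending file location for
    missing columns, non-numeric cells and duplicate pose indices.
    """
    path = Path(path)
    if not path.exists():
        raise JointcalError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise JointcalError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise JointcalError(f"{path}: no samples")

    frames = df["frame"].str.strip().unique()
    if len(frames) != 1:
        raise JointcalError(f"{path}: mixed frame labels {sorted(frames)}")
    frame = str(frames[0])
    if expected_frame is not None and frame != expected_frame:
        raise JointcalError(f"{path}: frame is {frame!r}, expected {expected_frame!r}")

    idx = _parse_numeric(df, "pose_index", path)
    if not np.all(idx == np.round(idx)):
        raise JointcalError(f"{path}: pose_index must be integer")
    idx = idx.astype(int)
    dup = pd.Series(idx).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise JointcalError(f"{path}:{row + 2}: duplicate pose_index {idx[row]}")

    xyz = np.column_stack([_parse_numeric(df, c, path) for c in ("x_mm", "y_mm", "z_mm")])
    orientations = None
    if all(c in df.columns for c in ORIENTATION_COLUMNS):
        orientations = np.column_stack(
            [_parse_numeric(df, c, path) for c in ORIENTATION_COLUMNS]
        )
    return PointSet(frame=frame, points=xyz, pose_indices=idx, orientations=orientations)


def write_trajectory_csv(path: str | Path, points: PointSet) -> None:
    """Write a :class:`PointSet` in the marker CSV schema (full precision)."""
    path = Path(path)
    idx = points.pose_indices
    if idx is None:
        idx = np.arange(1, len(points) + 1)
    data = {
        "frame": [points.frame] * len(points),
        "pose_index": idx,
        "x_mm": points.points[:, 0],
        "y_mm": points.points[:, 1],
        "z_mm": points.points[:, 2],
    }
    if points.orientations is not None:
        for k, c in enumerate(ORIENTATION_COLUMNS):
            data[c] = points.orientations[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def transform_to_dict(t: FrameTransform) -> dict:
    return {
        "linear_map_row_major": [float(v) for v in t.linear_map.ravel()],
        "source_anchor": [float(v) for v in t.source_anchor],
        "target_anchor": [float(v) for v in t.target_anchor],
        "source_frame": t.source_frame,
        "target_frame": t.target_frame,
        "direction": t.direction,
        "residual_rms": float(t.residual_rms),
    }


def transform_from_dict(d: dict) -> FrameTransform:
    return FrameTransform(
        linear_map=np.array(d["linear_map_row_major"], dtype=float).reshape(3, 3),
        source_anchor=np.array(d["source_anchor"], dtype=float),
        target_anchor=np.array(d["target_anchor"], dtype=float),
        source_frame=d["source_frame"],
        target_frame=d["target_frame"],
        residual_rms=float(d.get("residual_rms", 0.0)),
    )


def write_transform_json(path: str | Path, t: FrameTransform) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=2))


def read_transform_json(path: str | Path) -> FrameTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


def result_to_dict(result: CalibrationResult) -> dict:
    d: dict = {
        "method": result.method,
        "transform": transform_to_dict(result.transform),
    }
    if result.tcp is not None:
        d["tcp_mm"] = [float(v) for v in result.tcp]
    if result.lot is not None:
        d["lot_mm"] = float(result.lot)
    if result.origin_deviation is not None:
        d["origin_deviation_mm"] = [float(v) for v in result.origin_deviation]
    if result.sphere_report is not None:
        d["sphere_report"] = result.sphere_report.to_dict()
    if result.trajectory_robot is not None:
        d["trajectory_robot_n"] = int(len(result.trajectory_robot))
    if result.plane_fits:
        d["plane_fits"] = {
            label: {
                "unit_normal": [float(v) for v in p.unit_normal],
                "offset_mm": float(p.offset),
                "rms_residual_mm": float(p.rms_residual),
            }
            for label, p in result.plane_fits.items()
        }
    return d


def write_result_json(path: str | Path, result: CalibrationResult, config: RunConfig | None = None) -> None:
    d = result_to_dict(result)
    if config is not None:
        d["config"] = asdict(config)
    Path(path).write_text(json.dumps(d, indent=2))
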