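"""Trajectory containers, landmark-layout mapping and file I/O.

Pose-estimation backends emit different landmark sets (MediaPipe Pose: 33,
HybrIK/SMPL: 29, Human3.6M-style transformers: 17).  This module maps any of
them onto the canonical 12-joint skeleton (left/right shoulder, elbow, wrist,
hip, knee, ankle) plus the derived pelvis and shoulder centers, and reads and
writes the package's plain-text formats:

* trajectory CSV — one row per frame, columns ``<joint>_{x,y,z}``;
* trajectory JSON — either a list of per-frame ``{joint: [x, y, z]}`` maps
  (canonical) or a list of per-frame landmark arrays (backend layouts);
* angle CSV — the 21 pose variables per frame, degrees (gamma dimensionless).

Coordinate convention: right-handed, origin at the pelvis center, +y up,
+x toward the subject's anatomical left, +z toward the camera.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .humanoid import CANONICAL_JOINTS, AUXILIARY_JOINTS, POSE_VARIABLE_NAMES

__all__ = [
    "Trajectory",
    "LandmarkLayout",
    "LAYOUTS",
    "read_trajectory",
    "write_trajectory",
    "write_angles",
    "read_angles",
]

ALL_JOINTS = CANONICAL_JOINTS + AUXILIARY_JOINTS


class TrajectoryParseError(ValueError):
    """Malformed trajectory file."""


class LayoutError(ValueError):
    """Landmark layout inconsistent with the data."""


@dataclass(frozen=True)
class LandmarkLayout:
    """Maps canonical joint names to source landmark indices."""

    name: str
    n_landmarks: int
    index_map: dict[str, int]

    def __post_init__(self):
        missing = set(CANONICAL_JOINTS) - set(self.index_map)
        if missing:
            raise LayoutError(f"layout {self.name}: unmapped joints {sorted(missing)}")
        for joint, idx in self.index_map.items():
            if not 0 <= idx < self.n_landmarks:
                raise LayoutError(
                    f"layout {self.name}: index {idx} for {joint} outside "
                    f"0..{self.n_landmarks - 1}"
                )
        vals = [self.index_map[j] for j in CANONICAL_JOINTS]
        if len(set(vals)) != len(vals):
            raise LayoutError(f"layout {self.name}: duplicate landmark indices")


# MediaPipe Pose world landmarks (33).
_MPP33 = {
    "l_shoulder": 11, "r_shoulder": 12, "l_elbow": 13, "r_elbow": 14,
    "l_wrist": 15, "r_wrist": 16, "l_hip": 23, "r_hip": 24,
    "l_knee": 25, "r_knee": 26, "l_ankle": 27, "r_ankle": 28,
}
# HybrIK 29-point skeleton follows the SMPL joint ordering for its first 24
# entries; the backend does not document which of the 29 it reports for these
# joints, so the SMPL convention is the default and a user map can override.
_HYBRIK29 = {
    "l_hip": 1, "r_hip": 2, "l_knee": 4, "r_knee": 5,
    "l_ankle": 7, "r_ankle": 8, "l_shoulder": 16, "r_shoulder": 17,
    "l_elbow": 18, "r_elbow": 19, "l_wrist": 20, "r_wrist": 21,
}
# Standard Human3.6M 17-joint ordering (MHFormer, D3DP and kin).
_H36M17 = {
    "r_hip": 1, "r_knee": 2, "r_ankle": 3, "l_hip": 4, "l_knee": 5,
    "l_ankle": 6, "l_shoulder": 11, "l_elbow": 12, "l_wrist": 13,
    "r_shoulder": 14, "r_elbow": 15, "r_wrist": 16,
}

LAYOUTS: dict[str, LandmarkLayout] = {
    "mpp33": LandmarkLayout("mpp33", 33, _MPP33),
    "hybrik29": LandmarkLayout("hybrik29", 29, _HYBRIK29),
    "h36m17": LandmarkLayout("h36m17", 17, _H36M17),
    "canonical12": LandmarkLayout(
        "canonical12", 12, {j: i for i, j in enumerate(CANONICAL_JOINTS)}
    ),
}


@dataclass
class Trajectory:
    """Per-frame 3D joint coordinates.

    data maps joint name -> (n_frames, 3) float array.  The derived centers
    (pelvis_center = hip midpoint, shoulder_center = shoulder midpoint) are
    filled in automatically when absent.
    """

    data: dict[str, np.ndarray]
    fps: float = 30.0
    units: str = "meters"          # or "pixels"
    origin: str = "pelvis_center"  # or "image"

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.units not in ("meters", "pixels"):
            raise ValueError(f"unknown units {self.units!r}")
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        lengths = {v.shape[0] for v in self.data.values()}
        if len(lengths) != 1:
            raise ValueError("all joints must cover the same frames")
        if next(iter(lengths)) < 1:
            raise ValueError("trajectory needs at least one frame")
        for k, v in self.data.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"joint {k}: expected (n_frames, 3) array")
        missing = set(CANONICAL_JOINTS) - set(self.data)
        if missing:
            raise ValueError(f"missing canonical joints: {sorted(missing)}")
        if "pelvis_center" not in self.data:
            self.data["pelvis_center"] = 0.5 * (self.data["l_hip"] + self.data["r_hip"])
        if "shoulder_center" not in self.data:
            self.data["shoulder_center"] = 0.5 * (
                self.data["l_shoulder"] + self.data["r_shoulder"]
            )

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {k: v[i] for k, v in self.data.items()}

    def copy(self) -> "Trajectory":
        return Trajectory({k: v.copy() for k, v in self.data.items()},
                          fps=self.fps, units=self.units, origin=self.origin)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for j in ALL_JOINTS:
            for k, ax in enumerate("xyz"):
                cols[f"{j}_{ax}"] = self.data[j][:, k]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "Trajectory":
        data = {}
        joints = sorted({c[:-2] for c in df.columns if c[-2:] in ("_x", "_y", "_z")})
        for j in joints:
            cols = [f"{j}_{ax}" for ax in "xyz"]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise TrajectoryParseError(f"missing column(s) {missing}")
            data[j] = df[cols].to_numpy(dtype=float)
        return cls(data, **kw)

    @classmethod
    def from_frames(cls, frames: list[dict[str, np.ndarray]], **kw) -> "Trajectory":
        if not frames:
            raise ValueError("need at least one frame")
        joints = frames[0].keys()
        data = {j: np.stack([np.asarray(f[j], float) for f in frames]) for j in joints}
        return cls(data, **kw)


def read_trajectory(
    path: str | Path,
    layout: LandmarkLayout | str = "canonical12",
    *,
    fps: float = 30.0,
    units: str = "meters",
    origin: str = "pelvis_center",
) -> Trajectory:
    """Read a trajectory CSV/JSON and restrict it to the canonical joints.

    CSV files must already use canonical joint columns.  JSON files may be
    per-frame joint maps (canonical) or per-frame landmark arrays, which are
    mapped through ``layout.index_map``.
    """
    if isinstance(layout, str):
        try:
            layout = LAYOUTS[layout]
        except KeyError:
            raise LayoutError(f"unknown layout {layout!r}") from None
    path = Path(path)
    if path.suffix.lower() == ".json":
        frames = json.loads(path.read_text())
        if not isinstance(frames, list) or not frames:
            raise TrajectoryParseError(f"{path}: expected a non-empty JSON list")
        if isinstance(frames[0], dict):
            parsed = []
            for i, fr in enumerate(frames):
                missing = set(CANONICAL_JOINTS) - set(fr)
                if missing:
                    raise TrajectoryParseError(
                        f"{path}: frame {i} missing joints {sorted(missing)}"
                    )
                parsed.append({j: np.asarray(fr[j], float) for j in fr})
            return Trajectory.from_frames(parsed, fps=fps, units=units, origin=origin)
        parsed = []
        for i, fr in enumerate(frames):
            arr = np.asarray(fr, dtype=float)
            if arr.shape != (layout.n_landmarks, 3):
                raise LayoutError(
                    f"{path}: frame {i} has shape {arr.shape}, layout "
                    f"{layout.name} expects ({layout.n_landmarks}, 3)"
                )
            parsed.append({j: arr[idx] for j, idx in layout.index_map.items()})
        return Trajectory.from_frames(parsed, fps=fps, units=units, origin=origin)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    needed = [f"{j}_{ax}" for j in CANONICAL_JOINTS for ax in "xyz"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing column(s) {missing}")
    bad = df[needed].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise TrajectoryParseError(f"{path}: non-numeric or missing value in row {row}")
    return Trajectory.from_dataframe(df, fps=fps, units=units, origin=origin)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def write_angles(path: str | Path, angles, costs=None) -> None:
    """Write per-frame pose vectors as CSV (degrees; gamma dimensionless).

    ``angles`` is a non-empty sequence of PoseVector or 21-value sequences.
    """
    rows = []
    for a in angles:
        rows.append(a.values if hasattr(a, "values") else tuple(a))
    if not rows:
        raise ValueError("cannot write an empty angle list")
    df = pd.DataFrame(rows, columns=list(POSE_VARIABLE_NAMES))
    df.insert(0, "frame", range(len(rows)))
    if costs is not None:
        df["mpjpe_m"] = np.asarray(costs, dtype=float)
    df.to_csv(path, index=False, float_format="%.6f")


def read_angles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POSE_VARIABLE_NAMES if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing column(s) {missing}")
    return df
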