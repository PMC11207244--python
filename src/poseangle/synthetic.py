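"""Synthetic motion and corruption generator.

Ground truth for every pipeline stage: smooth multi-joint angle
trajectories (sinusoidal per-variable scripts evoking gym-style exercises —
rowing, back/chest pulls, alternating arm/leg raises) are rendered to 3D
joint coordinates through the humanoid forward kinematics, then corrupted
with the failure modes real pose backends exhibit: left/right identity
switches over frame segments (full-body or partial), end-joint misdetection
displacements, and Gaussian coordinate jitter.  The exact corrupted-frame
mask is returned alongside, so detector recall/precision and corrector
accuracy are measurable without any external footage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .humanoid import (
    DEFAULT_ANGLE_BOUNDS_DEG,
    POSE_VARIABLE_NAMES,
    HumanoidSpec,
    PoseVector,
    forward_kinematics,
    check_bounds,
)
from .io import Trajectory
from .outliers import OutlierMask

__all__ = [
    "MotionScript",
    "SwitchEvent",
    "MisdetectionEvent",
    "CorruptionSpec",
    "generate_motion",
    "corrupt",
    "default_script",
    "DEFAULT_SCRIPTS",
]

#: Left/right joint pairs swapped by a full switch.
_LR_PAIRS = (
    ("l_shoulder", "r_shoulder"), ("l_elbow", "r_elbow"), ("l_wrist", "r_wrist"),
    ("l_hip", "r_hip"), ("l_knee", "r_knee"), ("l_ankle", "r_ankle"),
)


@dataclass(frozen=True)
class Sinusoid:
    """angle(t) = offset + amplitude * sin(2*pi*t/period + phase), degrees."""

    amplitude_deg: float = 0.0
    period_s: float = 2.0
    phase_rad: float = 0.0
    offset_deg: float = 0.0

    def sample(self, t: np.ndarray) -> np.ndarray:
        return self.offset_deg + self.amplitude_deg * np.sin(
            2 * np.pi * t / self.period_s + self.phase_rad
        )


@dataclass
class MotionScript:
    """Per-variable sinusoidal angle generators for a motion sequence."""

    curves: dict[str, Sinusoid]
    duration_frames: int = 90
    fps: float = 30.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.duration_frames < 1 or self.fps <= 0:
            raise ValueError("need duration_frames >= 1 and fps > 0")
        unknown = set(self.curves) - set(POSE_VARIABLE_NAMES[1:])
        if unknown:
            raise ValueError(f"unknown pose variables {sorted(unknown)}")


@dataclass(frozen=True)
class SwitchEvent:
    """Left/right identity swap over [start, stop] (inclusive).

    ``pairs=None`` swaps every left/right pair (a full-body switch); a tuple
    of pair names like ("shoulder",) swaps only those joints (a partial
    switch, which breaks cross-body link lengths).
    """

    start: int
    stop: int
    pairs: tuple[str, ...] | None = None


@dataclass(frozen=True)
class MisdetectionEvent:
    """Displace one joint by a fixed offset over [start, stop]."""

    joint: str
    start: int
    stop: int
    displacement: tuple[float, float, float] = (0.3, 0.0, 0.0)


@dataclass
class CorruptionSpec:
    switches: list[SwitchEvent] = field(default_factory=list)
    misdetections: list[MisdetectionEvent] = field(default_factory=list)
    jitter_sigma_m: float = 0.0
    seed: int = 0


def generate_motion(
    script: MotionScript, spec: HumanoidSpec | None = None
) -> tuple[list[PoseVector], Trajectory]:
    """Sample the script and render it to joint coordinates via FK.

    Returns (ground-truth pose vectors, clean metric trajectory).  A script
    that leaves the configured angle bounds raises, naming the variable and
    frame.
    """
    if spec is None:
        spec = HumanoidSpec()
    t = np.arange(script.duration_frames) / script.fps
    angle_rows = np.zeros((script.duration_frames, len(POSE_VARIABLE_NAMES)))
    angle_rows[:, 0] = script.gamma
    for name, curve in script.curves.items():
        angle_rows[:, POSE_VARIABLE_NAMES.index(name)] = curve.sample(t)
    poses, frames = [], []
    for i in range(script.duration_frames):
        pose = PoseVector(tuple(angle_rows[i]))
        try:
            check_bounds(pose, spec)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        poses.append(pose)
        frames.append(forward_kinematics(pose, spec, validate=False))
    traj = Trajectory.from_frames(frames, fps=script.fps, units="meters")
    return poses, traj


def corrupt(
    traj: Trajectory, corruption: CorruptionSpec
) -> tuple[Trajectory, OutlierMask]:
    """Apply switches, misdetections and jitter; return the truth mask.

    Frames touched by a switch or misdetection are flagged; jitter is not
    (it is noise, not an outlier).  With no events and sigma = 0 the output
    equals the input and the mask is empty.
    """
    rng = np.random.default_rng(corruption.seed)
    out = traj.copy()
    n = out.n_frames
    flags = np.zeros(n, dtype=bool)
    for ev in corruption.switches:
        if not (0 <= ev.start <= ev.stop < n):
            raise ValueError(f"switch segment [{ev.start}, {ev.stop}] outside trajectory")
        pairs = _LR_PAIRS if ev.pairs is None else tuple(
            (f"l_{p}", f"r_{p}") for p in ev.pairs
        )
        sl = slice(ev.start, ev.stop + 1)
        for a, b in pairs:
            out.data[a][sl], out.data[b][sl] = (
                out.data[b][sl].copy(), out.data[a][sl].copy(),
            )
        flags[sl] = True
    for ev in corruption.misdetections:
        if not (0 <= ev.start <= ev.stop < n):
            raise ValueError(
                f"misdetection segment [{ev.start}, {ev.stop}] outside trajectory"
            )
        out.data[ev.joint][ev.start:ev.stop + 1] += np.asarray(ev.displacement, float)
        flags[ev.start:ev.stop + 1] = True
    if corruption.jitter_sigma_m > 0:
        for j in out.data:
            out.data[j] = out.data[j] + rng.normal(
                0.0, corruption.jitter_sigma_m, size=out.data[j].shape
            )
    # rebuild derived centers so they stay consistent with the corrupted hips
    out.data["pelvis_center"] = 0.5 * (out.data["l_hip"] + out.data["r_hip"])
    out.data["shoulder_center"] = 0.5 * (out.data["l_shoulder"] + out.data["r_shoulder"])
    segments = _segments_from_flags(flags)
    return out, OutlierMask(flags, segments)


def _segments_from_flags(flags: np.ndarray):
    from .outliers import OutlierSegment

    segs = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return segs
    start = prev = int(idx[0])
    for f in idx[1:]:
        if f == prev + 1:
            prev = int(f)
            continue
        segs.append(OutlierSegment(start, prev, (), "truth"))
        start = prev = int(f)
    segs.append(OutlierSegment(start, prev, (), "truth"))
    return segs


def default_script(name: str, *, duration_frames: int = 90, fps: float = 30.0) -> MotionScript:
    """Built-in motion scripts: 'rowing', 'back_chest', 'arm_leg', 'still'."""
    s = DEFAULT_SCRIPTS.get(name)
    if s is None:
        raise KeyError(f"unknown script {name!r}; have {sorted(DEFAULT_SCRIPTS)}")
    return MotionScript(dict(s), duration_frames=duration_frames, fps=fps)


# Amplitudes/periods are the package's own stand-ins for gym-style motions;
# all curves stay inside the default angle bounds.
DEFAULT_SCRIPTS: dict[str, dict[str, Sinusoid]] = {
    "rowing": {
        "theta_ws": Sinusoid(20.0, 2.0, 0.0, 15.0),
        "theta_sh_l": Sinusoid(35.0, 2.0, np.pi, 40.0),
        "theta_sh_r": Sinusoid(35.0, 2.0, np.pi, 40.0),
        "theta_el_l": Sinusoid(40.0, 2.0, 0.0, 60.0),
        "theta_el_r": Sinusoid(40.0, 2.0, 0.0, 60.0),
        "theta_hp_l": Sinusoid(15.0, 2.0, 0.0, 20.0),
        "theta_hp_r": Sinusoid(15.0, 2.0, 0.0, 20.0),
        "theta_kn_l": Sinusoid(20.0, 2.0, 0.0, 25.0),
        "theta_kn_r": Sinusoid(20.0, 2.0, 0.0, 25.0),
    },
    "back_chest": {
        "theta_sh_l": Sinusoid(50.0, 2.5, 0.0, 70.0),
        "theta_sh_r": Sinusoid(50.0, 2.5, 0.0, 70.0),
        "phi_sh_l": Sinusoid(35.0, 2.5, np.pi / 2, 50.0),
        "phi_sh_r": Sinusoid(35.0, 2.5, np.pi / 2, 50.0),
        "theta_el_l": Sinusoid(45.0, 2.5, np.pi, 65.0),
        "theta_el_r": Sinusoid(45.0, 2.5, np.pi, 65.0),
        "theta_ws": Sinusoid(8.0, 2.5, 0.0, 0.0),
    },
    "arm_leg": {
        "theta_sh_l": Sinusoid(60.0, 2.0, 0.0, 45.0),
        "theta_sh_r": Sinusoid(60.0, 2.0, np.pi, 45.0),
        "theta_el_l": Sinusoid(25.0, 2.0, 0.0, 35.0),
        "theta_el_r": Sinusoid(25.0, 2.0, np.pi, 35.0),
        "theta_hp_l": Sinusoid(30.0, 2.0, np.pi, 35.0),
        "theta_hp_r": Sinusoid(30.0, 2.0, 0.0, 35.0),
        "theta_kn_l": Sinusoid(30.0, 2.0, 0.0, 40.0),
        "theta_kn_r": Sinusoid(30.0, 2.0, np.pi, 40.0),
        "phi_hp_l": Sinusoid(10.0, 2.0, 0.0, 12.0),
        "phi_hp_r": Sinusoid(10.0, 2.0, np.pi, 12.0),
    },
    "still": {},
}
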