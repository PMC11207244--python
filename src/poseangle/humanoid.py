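"""26-DoF humanoid forward kinematics.

The skeleton is a pair of kinematic trees rooted at the pelvis center:
pelvis -> waist -> shoulder center -> {left,right} shoulder -> elbow -> wrist,
and pelvis -> {left,right} hip -> knee -> ankle.  Each joint variable rotates
in one anatomical plane: sagittal (``theta``, about the mediolateral x axis),
coronal (``phi``, about the anteroposterior z axis) or transverse (``psi``,
about the vertical y axis).  Multi-DoF joints compose their rotations
intrinsically in the order sagittal, coronal, transverse.  The world frame is
right-handed with the origin at the pelvis center, +y up, +x toward the
subject's anatomical left and +z toward the camera.

A global size factor ``gamma`` multiplies every link length, absorbing the
unknown camera distance: the same pose seen from farther away is a smaller
skeleton, not a different one.

Of the 26 joint variables, 20 (3 body-orientation angles, 3 waist angles and
14 limb angles) plus ``gamma`` form the 21-entry pose vector that the fitter
optimizes; the remaining 6 (neck coronal/transverse, hip transverse pair,
ankle sagittal pair) are held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HumanoidSpec",
    "PoseVector",
    "POSE_VARIABLE_NAMES",
    "ALL_DOF_NAMES",
    "OPTIMIZED_JOINT_ANGLES",
    "CANONICAL_JOINTS",
    "DEFAULT_ANGLE_BOUNDS_DEG",
    "forward_kinematics",
    "mirror_pose",
]

#: The 12 canonical joints the cost function compares, plus the two derived
#: centers (pelvis center is the FK origin; shoulder center carries the trunk).
CANONICAL_JOINTS = (
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
)
AUXILIARY_JOINTS = ("pelvis_center", "shoulder_center")

#: The 21 optimization variables in their canonical printed order:
#: size factor, body angles, waist angles, then sagittal hip/knee (l, r),
#: sagittal shoulder/elbow (l, r), coronal hip, coronal shoulder and
#: transverse shoulder pairs.
POSE_VARIABLE_NAMES = (
    "gamma",
    "theta_bd", "phi_bd", "psi_bd",
    "theta_ws", "phi_ws", "psi_ws",
    "theta_hp_l", "theta_kn_l", "theta_hp_r", "theta_kn_r",
    "theta_sh_l", "theta_el_l", "theta_sh_r", "theta_el_r",
    "phi_hp_l", "phi_hp_r",
    "phi_sh_l", "phi_sh_r",
    "psi_sh_l", "psi_sh_r",
)

#: The 17 optimized joint angles (pose vector minus gamma and body angles).
OPTIMIZED_JOINT_ANGLES = POSE_VARIABLE_NAMES[4:]

#: All 26 joint degrees of freedom.  The six not present in the pose vector
#: (neck coronal/transverse, transverse hips, sagittal ankles) are held at 0.
ALL_DOF_NAMES = POSE_VARIABLE_NAMES[1:] + (
    "phi_nk", "psi_nk", "psi_hp_l", "psi_hp_r", "theta_an_l", "theta_an_r",
)

DEFAULT_ANGLE_BOUNDS_DEG: dict[str, tuple[float, float]] = {
    "theta_bd": (-60.0, 60.0),
    "phi_bd": (-45.0, 45.0),
    "psi_bd": (-90.0, 90.0),
    "theta_ws": (-45.0, 60.0),
    "phi_ws": (-40.0, 40.0),
    "psi_ws": (-45.0, 45.0),
    "theta_hp_l": (-30.0, 120.0),
    "theta_hp_r": (-30.0, 120.0),
    "theta_kn_l": (0.0, 150.0),
    "theta_kn_r": (0.0, 150.0),
    "theta_sh_l": (-60.0, 180.0),
    "theta_sh_r": (-60.0, 180.0),
    "theta_el_l": (0.0, 150.0),
    "theta_el_r": (0.0, 150.0),
    "phi_hp_l": (-45.0, 45.0),
    "phi_hp_r": (-45.0, 45.0),
    "phi_sh_l": (-45.0, 170.0),
    "phi_sh_r": (-45.0, 170.0),
    "psi_sh_l": (-90.0, 90.0),
    "psi_sh_r": (-90.0, 90.0),
}
GAMMA_BOUNDS = (0.5, 2.0)

# Anthropometric segment lengths as fractions of stature (standard
# proportional tables); the reference is an unpublished parameter set, so
# these defaults are the package's own convention and fully overridable.
_FRACTIONS = {
    "pelvis_half_width": 0.191 / 2,
    "shoulder_half_width": 0.259 / 2,
    "trunk": 0.288,
    "neck": 0.052,
    "upper_arm": 0.186,
    "lower_arm": 0.146,
    "thigh": 0.245,
    "shin": 0.246,
}


@dataclass(frozen=True)
class HumanoidSpec:
    """Link lengths (cm, at gamma = 1) and angle bounds of the humanoid.

    Defaults derive each segment from ``stature_cm`` by standard
    anthropometric fractions; pass explicit lengths to override.  Left and
    right limbs share lengths (the skeleton is bilaterally symmetric).
    """

    stature_cm: float = 175.0
    pelvis_half_width_cm: float | None = None
    shoulder_half_width_cm: float | None = None
    trunk_cm: float | None = None
    neck_cm: float | None = None
    upper_arm_cm: float | None = None
    lower_arm_cm: float | None = None
    thigh_cm: float | None = None
    shin_cm: float | None = None
    angle_bounds_deg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANGLE_BOUNDS_DEG)
    )
    gamma_bounds: tuple[float, float] = GAMMA_BOUNDS

    def __post_init__(self):
        if self.stature_cm <= 0:
            raise ValueError("stature_cm must be positive")
        for key, frac in _FRACTIONS.items():
            attr = f"{key}_cm"
            if getattr(self, attr) is None:
                object.__setattr__(self, attr, frac * self.stature_cm)
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @property
    def n_dof(self) -> int:
        """Number of joint degrees of freedom in the model."""
        return len(ALL_DOF_NAMES)

    def bounds_vector(self) -> list[tuple[float, float]]:
        """Per-variable (lo, hi) bounds in pose-vector order."""
        out = [self.gamma_bounds]
        out += [self.angle_bounds_deg[n] for n in POSE_VARIABLE_NAMES[1:]]
        return out


@dataclass(frozen=True)
class PoseVector:
    """The 21 optimization variables: gamma plus 20 angles in degrees."""

    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != len(POSE_VARIABLE_NAMES):
            raise ValueError(
                f"pose vector needs {len(POSE_VARIABLE_NAMES)} entries, "
                f"got {len(self.values)}"
            )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.values[0] <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PoseVector":
        return cls(tuple(d.get(n, 1.0 if n == "gamma" else 0.0)
                         for n in POSE_VARIABLE_NAMES))

    @classmethod
    def reference(cls) -> "PoseVector":
        """Upright zero pose, gamma = 1."""
        return cls((1.0,) + (0.0,) * 20)

    def __getitem__(self, name: str) -> float:
        return self.values[POSE_VARIABLE_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(POSE_VARIABLE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _rx(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _joint_rotation(theta: float, phi: float, psi: float) -> np.ndarray:
    # intrinsic sagittal -> coronal -> transverse
    return _rx(theta) @ _rz(phi) @ _ry(psi)


def check_bounds(pose: PoseVector, spec: HumanoidSpec) -> None:
    """Raise ValueError naming the first out-of-bounds variable."""
    for name, value, (lo, hi) in zip(
        POSE_VARIABLE_NAMES, pose.values, spec.bounds_vector()
    ):
        if not (lo <= value <= hi):
            raise ValueError(
                f"pose variable {name}={value:g} outside bounds [{lo:g}, {hi:g}]"
            )


def forward_kinematics(
    pose: PoseVector,
    spec: HumanoidSpec | None = None,
    *,
    validate: bool = True,
) -> dict[str, np.ndarray]:
    """Joint positions (meters) of the 12 canonical joints plus centers.

    The pelvis center sits at the origin.  Body orientation
    ``Ry(psi_bd) Rz(phi_bd) Rx(theta_bd)`` pre-rotates both trees; every link
    length is ``gamma`` times the spec length.

    Parameters
    ----------
    pose
        The 21-variable pose; angles in degrees.
    spec
        Skeleton dimensions; default anthropometry at 175 cm stature.
    validate
        When true, out-of-bounds variables raise ``ValueError``.
    """
    if spec is None:
        spec = HumanoidSpec()
    if validate:
        check_bounds(pose, spec)
    p = pose.as_dict()
    g = p["gamma"] * 0.01  # cm -> m, scaled

    pw = spec.pelvis_half_width_cm * g
    sw = spec.shoulder_half_width_cm * g
    trunk = spec.trunk_cm * g
    ua = spec.upper_arm_cm * g
    la = spec.lower_arm_cm * g
    th = spec.thigh_cm * g
    sh = spec.shin_cm * g

    r_body = _ry(p["psi_bd"]) @ _rz(p["phi_bd"]) @ _rx(p["theta_bd"])
    joints: dict[str, np.ndarray] = {"pelvis_center": np.zeros(3)}

    # lower tree
    for side, sgn in (("l", +1.0), ("r", -1.0)):
        hip = r_body @ np.array([sgn * pw, 0.0, 0.0])
        r_hip = r_body @ _joint_rotation(
            p[f"theta_hp_{side}"], p[f"phi_hp_{side}"], 0.0
        )
        knee = hip + r_hip @ np.array([0.0, -th, 0.0])
        r_knee = r_hip @ _rx(p[f"theta_kn_{side}"])
        ankle = knee + r_knee @ np.array([0.0, -sh, 0.0])
        joints[f"{side}_hip"] = hip
        joints[f"{side}_knee"] = knee
        joints[f"{side}_ankle"] = ankle

    # upper tree: the 3-DoF waist joint sits at the pelvis center
    r_waist = r_body @ _joint_rotation(p["theta_ws"], p["phi_ws"], p["psi_ws"])
    shoulder_center = r_waist @ np.array([0.0, trunk, 0.0])
    joints["shoulder_center"] = shoulder_center
    for side, sgn in (("l", +1.0), ("r", -1.0)):
        shoulder = shoulder_center + r_waist @ np.array([sgn * sw, 0.0, 0.0])
        r_sh = r_waist @ _joint_rotation(
            p[f"theta_sh_{side}"], p[f"phi_sh_{side}"], p[f"psi_sh_{side}"]
        )
        elbow = shoulder + r_sh @ np.array([0.0, -ua, 0.0])
        r_el = r_sh @ _rx(p[f"theta_el_{side}"])
        wrist = elbow + r_el @ np.array([0.0, -la, 0.0])
        joints[f"{side}_shoulder"] = shoulder
        joints[f"{side}_elbow"] = elbow
        joints[f"{side}_wrist"] = wrist

    return joints


#: Row order of the fast FK array (the 12 canonical joints).
FK_JOINT_ORDER = CANONICAL_JOINTS


def fk_canonical(values: np.ndarray, spec: HumanoidSpec) -> np.ndarray:
    """Positions of the 12 canonical joints as a (12, 3) array.

    Fast path for the fitting cost: same kinematics as
    :func:`forward_kinematics`, no validation, no dict construction.
    Row order follows :data:`FK_JOINT_ORDER`.
    """
    (gamma, theta_bd, phi_bd, psi_bd, theta_ws, phi_ws, psi_ws,
     theta_hp_l, theta_kn_l, theta_hp_r, theta_kn_r,
     theta_sh_l, theta_el_l, theta_sh_r, theta_el_r,
     phi_hp_l, phi_hp_r, phi_sh_l, phi_sh_r, psi_sh_l, psi_sh_r) = values
    g = gamma * 0.01
    pw = spec.pelvis_half_width_cm * g
    sw = spec.shoulder_half_width_cm * g
    trunk = spec.trunk_cm * g
    ua = spec.upper_arm_cm * g
    la = spec.lower_arm_cm * g
    th = spec.thigh_cm * g
    shn = spec.shin_cm * g

    r_body = _ry(psi_bd) @ _rz(phi_bd) @ _rx(theta_bd)
    out = np.empty((12, 3))
    # rows: l_sh, r_sh, l_el, r_el, l_wr, r_wr, l_hp, r_hp, l_kn, r_kn, l_an, r_an
    down_th = np.array([0.0, -th, 0.0])
    down_shn = np.array([0.0, -shn, 0.0])
    down_ua = np.array([0.0, -ua, 0.0])
    down_la = np.array([0.0, -la, 0.0])
    for k, (sgn, t_hp, t_kn, p_hp) in enumerate(
        ((+1.0, theta_hp_l, theta_kn_l, phi_hp_l),
         (-1.0, theta_hp_r, theta_kn_r, phi_hp_r))
    ):
        hip = r_body @ np.array([sgn * pw, 0.0, 0.0])
        r_hip = r_body @ _rx(t_hp) @ _rz(p_hp)
        knee = hip + r_hip @ down_th
        ankle = knee + r_hip @ _rx(t_kn) @ down_shn
        out[6 + k] = hip
        out[8 + k] = knee
        out[10 + k] = ankle
    r_waist = r_body @ _rx(theta_ws) @ _rz(phi_ws) @ _ry(psi_ws)
    sc = r_waist @ np.array([0.0, trunk, 0.0])
    for k, (sgn, t_sh, p_sh, s_sh, t_el) in enumerate(
        ((+1.0, theta_sh_l, phi_sh_l, psi_sh_l, theta_el_l),
         (-1.0, theta_sh_r, phi_sh_r, psi_sh_r, theta_el_r))
    ):
        shoulder = sc + r_waist @ np.array([sgn * sw, 0.0, 0.0])
        r_sh = r_waist @ _rx(t_sh) @ _rz(p_sh) @ _ry(s_sh)
        elbow = shoulder + r_sh @ down_ua
        wrist = elbow + r_sh @ _rx(t_el) @ down_la
        out[0 + k] = shoulder
        out[2 + k] = elbow
        out[4 + k] = wrist
    return out


_SAGITTAL_PAIRS = [
    ("theta_hp_l", "theta_hp_r"), ("theta_kn_l", "theta_kn_r"),
    ("theta_sh_l", "theta_sh_r"), ("theta_el_l", "theta_el_r"),
]
_NEGATING_PAIRS = [
    ("phi_hp_l", "phi_hp_r"), ("phi_sh_l", "phi_sh_r"),
    ("psi_sh_l", "psi_sh_r"),
]
_NEGATED_SOLO = ["phi_bd", "psi_bd", "phi_ws", "psi_ws"]


def mirror_pose(pose: PoseVector) -> PoseVector:
    """Left/right mirror: FK(mirror(pose)) is the x-negated FK(pose).

    Sagittal angles swap sides unchanged; coronal and transverse angles swap
    sides and flip sign; body/waist coronal and transverse terms flip sign.
    An involution; symmetric poses are fixed points.
    """
    d = pose.as_dict()
    for a, b in _SAGITTAL_PAIRS:
        d[a], d[b] = d[b], d[a]
    for a, b in _NEGATING_PAIRS:
        d[a], d[b] = -d[b], -d[a]
    for name in _NEGATED_SOLO:
        d[name] = -d[name]
    return PoseVector.from_dict(d)


def mirror_joints(joints: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Negate x and swap left/right joint names (test/plot utility)."""
    out = {}
    flip = np.array([-1.0, 1.0, 1.0])
    for name, xyz in joints.items():
        if name.startswith("l_"):
            tgt = "r_" + name[2:]
        elif name.startswith("r_"):
            tgt = "l_" + name[2:]
        else:
            tgt = name
        out[tgt] = xyz * flip
    return out
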