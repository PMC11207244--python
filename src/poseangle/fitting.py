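"""Per-frame joint-angle estimation by humanoid model fitting.

Each frame's measured 3D joints are compared to the forward kinematics of
the 26-DoF humanoid at a candidate 21-variable pose vector; the cost is the
MPJPE — the mean Euclidean distance over the 12 canonical joints:

    L(V) = (1/12) * sum_{i,j} || (x_e, y_e, z_e)_{i,j} - (x_s, y_s, z_s)_{i,j} ||

with i in {left, right} and j in {shoulder, elbow, wrist, hip, knee, ankle}.
uDEAS minimizes L(V) over the box of angle bounds; when the fitted and
measured skeletons overlap exactly the cost is zero.  Sequences are fitted
frame by frame, warm-starting each frame at the previous solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .humanoid import (
    CANONICAL_JOINTS,
    POSE_VARIABLE_NAMES,
    HumanoidSpec,
    PoseVector,
    forward_kinematics,
    fk_canonical,
    _rx,
    _ry,
    _rz,
)
from .io import Trajectory
from .udeas import OptimizerConfig, OptimizeResult, optimize

__all__ = ["PoseSolution", "AngleTrajectory", "mpjpe_cost", "fit_frame", "fit_sequence"]


@dataclass
class PoseSolution:
    """Best pose for one frame, its cost and the fitted joint positions."""

    pose: PoseVector
    cost: float                      # MPJPE, meters
    fitted: dict[str, np.ndarray]
    n_evals: int
    restart_costs: list[float] = field(default_factory=list)


@dataclass
class AngleTrajectory:
    solutions: list[PoseSolution]
    fps: float

    def __len__(self):
        return len(self.solutions)

    def angles(self) -> np.ndarray:
        """(n_frames, 21) array of pose vectors."""
        return np.array([s.pose.values for s in self.solutions])

    def costs(self) -> np.ndarray:
        return np.array([s.cost for s in self.solutions])


def center_frame(measured: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Re-express a frame in the pelvis-centered comparison frame."""
    if "pelvis_center" in measured:
        c = np.asarray(measured["pelvis_center"], float)
    else:
        c = 0.5 * (np.asarray(measured["l_hip"], float)
                   + np.asarray(measured["r_hip"], float))
    return {k: np.asarray(v, float) - c for k, v in measured.items()}


def mpjpe_cost(
    pose: PoseVector,
    measured: dict[str, np.ndarray],
    spec: HumanoidSpec | None = None,
    *,
    precentered: bool = False,
) -> float:
    """Mean per-joint position error (meters) over the 12 canonical joints."""
    missing = [j for j in CANONICAL_JOINTS if j not in measured]
    if missing:
        raise KeyError(f"measured frame missing joints {missing}")
    if not precentered:
        measured = center_frame(measured)
    fitted = forward_kinematics(pose, spec, validate=False)
    total = 0.0
    for j in CANONICAL_JOINTS:
        total += float(np.linalg.norm(measured[j] - fitted[j]))
    return total / len(CANONICAL_JOINTS)


def _cost_closure(measured, spec):
    centered = center_frame(measured)
    tgt = np.stack([centered[j] for j in CANONICAL_JOINTS])

    def cost(x: np.ndarray) -> float:
        diff = tgt - fk_canonical(x, spec)
        return float(np.mean(np.sqrt(np.einsum("ij,ij->i", diff, diff))))

    return cost


def _clip(v, lo, hi, margin=1e-6):
    span = hi - lo
    return float(min(max(v, lo + margin * span), hi - margin * span))


def initial_pose_estimate(
    measured: dict[str, np.ndarray], spec: HumanoidSpec | None = None
) -> PoseVector:
    """Closed-form geometric pose estimate from measured joint directions.

    Solves each chain's angles directly from limb unit vectors (size factor
    from link-length ratios, body yaw/roll from the hip line, waist from the
    trunk and shoulder lines, hip/shoulder/knee/elbow angles from segment
    directions expressed in their parent frames).  Body pitch is set to zero:
    the sagittal body angle is an exact gauge freedom of the skeleton (it
    composes with the adjacent waist and hip sagittal rotations), so any
    value on the orbit reproduces the same joints.  The result seeds the
    uDEAS search in the correct basin; values are clipped into bounds.
    """
    if spec is None:
        spec = HumanoidSpec()
    m = center_frame(measured)
    b = dict(zip(POSE_VARIABLE_NAMES, spec.bounds_vector()))

    def unit(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0, 0.0])

    # size factor from links whose spec length is fixed
    ratios = []
    for (a, bj), length_cm in (
        (("l_hip", "r_hip"), 2 * spec.pelvis_half_width_cm),
        (("l_shoulder", "r_shoulder"), 2 * spec.shoulder_half_width_cm),
        (("l_hip", "l_knee"), spec.thigh_cm),
        (("r_hip", "r_knee"), spec.thigh_cm),
        (("l_knee", "l_ankle"), spec.shin_cm),
        (("r_knee", "r_ankle"), spec.shin_cm),
        (("l_shoulder", "l_elbow"), spec.upper_arm_cm),
        (("r_shoulder", "r_elbow"), spec.upper_arm_cm),
        (("l_elbow", "l_wrist"), spec.lower_arm_cm),
        (("r_elbow", "r_wrist"), spec.lower_arm_cm),
    ):
        ratios.append(np.linalg.norm(m[a] - m[bj]) / (length_cm * 0.01))
    est = {"gamma": _clip(float(np.median(ratios)), *b["gamma"])}

    # Body orientation from the hip line.  The sagittal body angle is an
    # exact gauge freedom (it composes with the adjacent waist/hip sagittal
    # rotations), so compute all chains with it at zero first and shift the
    # gauge afterwards so the compensated angles fit their bounds.
    xb = unit(m["l_hip"] - m["r_hip"])
    est["phi_bd"] = _clip(np.rad2deg(np.arcsin(np.clip(xb[1], -1, 1))), *b["phi_bd"])
    est["psi_bd"] = _clip(np.rad2deg(np.arctan2(-xb[2], xb[0])), *b["psi_bd"])
    est["theta_bd"] = 0.0
    r_bd = _ry(est["psi_bd"]) @ _rz(est["phi_bd"])
    to_body = r_bd.T

    # waist from trunk and shoulder-line directions
    sc = m.get("shoulder_center", 0.5 * (m["l_shoulder"] + m["r_shoulder"]))
    ys = unit(to_body @ sc)
    s_line = to_body @ (m["l_shoulder"] - m["r_shoulder"])
    xs = unit(s_line - np.dot(s_line, ys) * ys)
    zs = np.cross(xs, ys)
    r_ws = np.column_stack([xs, ys, zs])
    est["phi_ws"] = _clip(
        np.rad2deg(np.arcsin(np.clip(-r_ws[0, 1], -1, 1))), *b["phi_ws"]
    )
    est["theta_ws"] = float(np.rad2deg(np.arctan2(r_ws[2, 1], r_ws[1, 1])))
    est["psi_ws"] = _clip(
        np.rad2deg(np.arctan2(r_ws[0, 2], r_ws[0, 0])), *b["psi_ws"]
    )
    to_waist = (r_bd @ _rx(est["theta_ws"]) @ _rz(est["phi_ws"])
                @ _ry(est["psi_ws"])).T

    for side in ("l", "r"):
        # hip and knee from thigh/shin directions in the body frame
        d = unit(to_body @ (m[f"{side}_knee"] - m[f"{side}_hip"]))
        phi = np.rad2deg(np.arcsin(np.clip(d[0], -1, 1)))
        theta = np.rad2deg(np.arctan2(-d[2], -d[1]))
        est[f"phi_hp_{side}"] = _clip(phi, *b[f"phi_hp_{side}"])
        est[f"theta_hp_{side}"] = float(theta)
        r_hp = r_bd @ _rx(est[f"theta_hp_{side}"]) @ _rz(est[f"phi_hp_{side}"])
        v = r_hp.T @ (m[f"{side}_ankle"] - m[f"{side}_knee"])
        est[f"theta_kn_{side}"] = _clip(
            np.rad2deg(np.arctan2(-v[2], -v[1])), *b[f"theta_kn_{side}"]
        )
        # Shoulder and elbow from arm directions in the waist frame.  The
        # swing decomposition u = (sin(phi), -cos(phi)cos(theta),
        # -cos(phi)sin(theta)) has two branches, (theta, phi) and
        # (theta + 180, 180 - phi); evaluate both and keep the one that
        # reproduces the measured elbow and wrist best after clipping.
        u_raw = to_waist @ (m[f"{side}_elbow"] - m[f"{side}_shoulder"])
        w_raw = to_waist @ (m[f"{side}_wrist"] - m[f"{side}_elbow"])
        u = unit(u_raw)
        phi1 = np.rad2deg(np.arcsin(np.clip(u[0], -1, 1)))
        theta1 = np.rad2deg(np.arctan2(-u[2], -u[1]))
        theta2 = theta1 - 180.0 if theta1 > 0 else theta1 + 180.0
        best = None
        for theta_c, phi_c in ((theta1, phi1), (theta2, 180.0 - phi1)):
            theta_c = _clip(theta_c, *b[f"theta_sh_{side}"])
            phi_c = _clip(phi_c, *b[f"phi_sh_{side}"])
            r_sw = _rx(theta_c) @ _rz(phi_c)
            v = r_sw.T @ w_raw
            el = np.rad2deg(np.arctan2(np.hypot(v[0], v[2]), -v[1]))
            el = _clip(el, *b[f"theta_el_{side}"])
            if np.hypot(v[0], v[2]) > 1e-6 * np.linalg.norm(v):
                psi = np.rad2deg(np.arctan2(-v[0], -v[2]))
            else:
                psi = 0.0  # straight arm: axial rotation unobservable
            psi = _clip(psi, *b[f"psi_sh_{side}"])
            ua = np.linalg.norm(u_raw)
            la = np.linalg.norm(w_raw)
            r_full = r_sw @ _ry(psi)
            pred_el = r_full @ np.array([0.0, -ua, 0.0])
            pred_wr = pred_el + r_full @ _rx(el) @ np.array([0.0, -la, 0.0])
            err = np.linalg.norm(pred_el - u_raw) + np.linalg.norm(
                pred_wr - (u_raw + w_raw)
            )
            if best is None or err < best[0]:
                best = (err, theta_c, phi_c, el, psi)
        _, est[f"theta_sh_{side}"], est[f"phi_sh_{side}"], \
            est[f"theta_el_{side}"], est[f"psi_sh_{side}"] = best

    # Gauge shift: pick the body sagittal angle delta so that the three
    # compensated sagittal angles (waist, both hips) all land inside their
    # bounds; delta = 0 is preferred when feasible.
    compensated = ("theta_ws", "theta_hp_l", "theta_hp_r")
    lo_d = max(est[n] - b[n][1] for n in compensated)
    hi_d = min(est[n] - b[n][0] for n in compensated)
    lo_d, hi_d = max(lo_d, b["theta_bd"][0]), min(hi_d, b["theta_bd"][1])
    delta = min(max(0.0, lo_d), hi_d) if lo_d <= hi_d else 0.0
    est["theta_bd"] = _clip(delta, *b["theta_bd"])
    for n in compensated:
        est[n] = _clip(est[n] - delta, *b[n])
    return PoseVector.from_dict(est)


def fit_frame(
    measured: dict[str, np.ndarray],
    spec: HumanoidSpec | None = None,
    config: OptimizerConfig | None = None,
    warm_start: PoseVector | None = None,
) -> PoseSolution:
    """Fit the 21-variable pose to one measured frame.

    The first restart's binary matrix encodes the warm start (the previous
    frame's pose, or, when none is given, the closed-form geometric estimate
    from the measured limb directions) at a depth a few levels below maximum
    so the search can still refine it; the remaining restarts are random.
    """
    if spec is None:
        spec = HumanoidSpec()
    if config is None:
        config = OptimizerConfig()
    missing = [j for j in CANONICAL_JOINTS if j not in measured]
    if missing:
        raise KeyError(f"measured frame missing joints {missing}")
    if warm_start is None:
        warm_start = initial_pose_estimate(measured, spec)
    cost = _cost_closure(measured, spec)
    res: OptimizeResult = optimize(
        cost, spec.bounds_vector(), config, warm_start=warm_start.as_array(),
    )
    pose = PoseVector(tuple(res.x))
    return PoseSolution(
        pose=pose,
        cost=cost(res.x),
        fitted=forward_kinematics(pose, spec, validate=False),
        n_evals=res.n_evals,
        restart_costs=res.restart_costs,
    )


def fit_sequence(
    traj: Trajectory,
    spec: HumanoidSpec | None = None,
    config: OptimizerConfig | None = None,
    *,
    warm_start: bool = True,
) -> AngleTrajectory:
    """Fit every frame in order, warm-starting from the previous solution."""
    if traj.units != "meters":
        raise ValueError("fit_sequence needs a metric (meters) trajectory")
    if config is None:
        config = OptimizerConfig()
    solutions: list[PoseSolution] = []
    prev: PoseVector | None = None
    for i in range(traj.n_frames):
        try:
            sol = fit_frame(
                traj.frame(i), spec, config,
                warm_start=prev if warm_start else None,
            )
        except Exception as exc:
            raise RuntimeError(f"pose fit failed at frame {i}: {exc}") from exc
        solutions.append(sol)
        prev = sol.pose
    return AngleTrajectory(solutions, fps=traj.fps)
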