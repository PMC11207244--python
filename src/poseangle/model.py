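"""Model/Results interface over the full joint-angle pipeline.

``JointAngleModel`` wraps a measured trajectory (plus optional detector
records) and, on ``fit()``, runs the three pipeline stages — ROI selection
and tracking when detections are supplied, link-length outlier detection
and correction, and per-frame uDEAS inverse kinematics — returning a
``JointAngleResults`` with the per-frame pose estimates, their MPJPE costs,
the outlier report and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .bbox import DetectionRecord, RoiTrack, track_sequence
from .config import PipelineConfig
from .fitting import AngleTrajectory, fit_sequence
from .humanoid import POSE_VARIABLE_NAMES, HumanoidSpec
from .io import (
    LandmarkLayout,
    Trajectory,
    read_trajectory,
    write_angles,
    write_trajectory,
)
from .outliers import OutlierMask, correct_trajectory, mask_report

__all__ = ["JointAngleModel", "JointAngleResults", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged failure of the end-to-end pipeline."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


class JointAngleModel:
    """Joint-angle estimation model for one measured trajectory.

    Parameters
    ----------
    trajectory
        Per-frame 3D joint coordinates (meters, pelvis-centered, from any
        supported pose backend).
    detections
        Optional per-frame detector records; used for ROI tracking and for
        the subject pixel height when the trajectory is in pixels.
    spec
        Humanoid skeleton dimensions; defaults to 175 cm anthropometry.
    config
        Pipeline settings (outlier threshold, median window, uDEAS
        optimizer parameters, ...).
    """

    def __init__(
        self,
        trajectory: Trajectory,
        detections: list[list[DetectionRecord]] | None = None,
        spec: HumanoidSpec | None = None,
        config: PipelineConfig | None = None,
    ):
        self.trajectory = trajectory
        self.detections = detections
        self.config = config if config is not None else PipelineConfig()
        if spec is None:
            spec = HumanoidSpec(stature_cm=self.config.assumed_stature_cm)
        if self.config.angle_bounds_deg:
            bounds = dict(spec.angle_bounds_deg)
            bounds.update(
                {k: tuple(v) for k, v in self.config.angle_bounds_deg.items()}
            )
            spec = HumanoidSpec(
                stature_cm=spec.stature_cm,
                pelvis_half_width_cm=spec.pelvis_half_width_cm,
                shoulder_half_width_cm=spec.shoulder_half_width_cm,
                trunk_cm=spec.trunk_cm,
                neck_cm=spec.neck_cm,
                upper_arm_cm=spec.upper_arm_cm,
                lower_arm_cm=spec.lower_arm_cm,
                thigh_cm=spec.thigh_cm,
                shin_cm=spec.shin_cm,
                angle_bounds_deg=bounds,
            )
        self.spec = spec

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        layout: LandmarkLayout | str = "canonical12",
        *,
        detections_path: str | Path | None = None,
        config: PipelineConfig | None = None,
        spec: HumanoidSpec | None = None,
        fps: float = 30.0,
        units: str = "meters",
    ) -> "JointAngleModel":
        traj = read_trajectory(path, layout, fps=fps, units=units)
        dets = None
        if detections_path is not None:
            from .bbox import read_detections

            dets = read_detections(detections_path)
        return cls(traj, detections=dets, spec=spec, config=config)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, fps: float = 30.0, units: str = "meters", **kw
    ) -> "JointAngleModel":
        return cls(Trajectory.from_dataframe(df, fps=fps, units=units), **kw)

    def track(self) -> RoiTrack | None:
        """Run ROI selection/tracking over the detection records, if any."""
        if self.detections is None:
            return None
        try:
            return track_sequence(
                self.detections,
                conf_threshold=self.config.conf_threshold,
                max_gap=self.config.max_track_gap,
            )
        except Exception as exc:
            raise PipelineError("bbox_tracking", exc) from exc

    def correct(self) -> tuple[Trajectory, OutlierMask, RoiTrack | None]:
        """Outlier detection and correction (with tracking if available)."""
        roi = self.track()
        pixel_height = None
        if roi is not None and self.trajectory.units == "pixels":
            pixel_height = float(np.median([b.height for b in roi.boxes]))
        cfg = self.config
        try:
            corrected, mask = correct_trajectory(
                self.trajectory,
                threshold_cm_per_frame=cfg.outlier_threshold_cm_per_frame,
                merge_gap=cfg.merge_gap,
                switch_link_count=cfg.switch_link_count,
                median_window=cfg.median_window,
                subject_pixel_height=pixel_height,
                stature_cm=cfg.assumed_stature_cm,
            )
        except Exception as exc:
            raise PipelineError("outlier_correction", exc) from exc
        return corrected, mask, roi

    def fit(self, *, correct: bool = True) -> "JointAngleResults":
        """Run the pipeline and fit per-frame joint angles.

        ``correct=False`` skips outlier correction and fits the raw input.
        """
        if correct:
            corrected, mask, roi = self.correct()
        else:
            corrected = self.trajectory
            mask = OutlierMask(np.zeros(self.trajectory.n_frames, dtype=bool))
            roi = self.track()
        try:
            angles = fit_sequence(
                corrected, self.spec, self.config.optimizer,
                warm_start=self.config.warm_start,
            )
        except Exception as exc:
            raise PipelineError("pose_fitting", exc) from exc
        return JointAngleResults(self, angles, corrected, mask, roi)


@dataclass
class JointAngleResults:
    """Fitted joint-angle trajectory with diagnostics."""

    model: JointAngleModel
    angle_trajectory: AngleTrajectory
    corrected: Trajectory
    outlier_mask: OutlierMask
    roi_track: RoiTrack | None = None

    @property
    def params(self) -> pd.DataFrame:
        """(n_frames, 21) pose variables; angles in degrees."""
        return pd.DataFrame(
            self.angle_trajectory.angles(), columns=list(POSE_VARIABLE_NAMES)
        )

    @property
    def costs(self) -> np.ndarray:
        """Per-frame MPJPE of the fitted pose, meters."""
        return self.angle_trajectory.costs()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Joint-angle estimation results",
            "=" * 66,
            f"frames fitted            {len(p):>10d}",
            f"mean MPJPE [m]           {self.costs.mean():>10.4f}",
            f"max MPJPE [m]            {self.costs.max():>10.4f}",
            f"flagged outlier frames   {int(self.outlier_mask.flags.sum()):>10d}",
            f"outlier segments         {len(self.outlier_mask.segments):>10d}",
            "-" * 66,
            f"{'variable':<12}{'mean':>12}{'std':>12}{'min':>12}{'max':>12}",
        ]
        for name in POSE_VARIABLE_NAMES:
            col = p[name]
            lines.append(
                f"{name:<12}{col.mean():>12.2f}{col.std(ddof=0):>12.2f}"
                f"{col.min():>12.2f}{col.max():>12.2f}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write angle CSV, corrected trajectory CSV and outlier JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "angles": out / "angles.csv",
            "corrected": out / "corrected_trajectory.csv",
            "outliers": out / "outlier_report.json",
        }
        write_angles(
            paths["angles"],
            [s.pose for s in self.angle_trajectory.solutions],
            costs=self.costs,
        )
        write_trajectory(paths["corrected"], self.corrected)
        paths["outliers"].write_text(
            json.dumps(mask_report(self.outlier_mask), indent=2)
        )
        return paths

    def plot_angles(self, variables=None, ax=None):
        """Plot fitted angle profiles over time (degrees vs seconds)."""
        import matplotlib.pyplot as plt

        if variables is None:
            variables = ["theta_ws", "theta_sh_l", "theta_el_l", "theta_kn_r"]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = np.arange(len(self.angle_trajectory)) / self.angle_trajectory.fps
        p = self.params
        for name in variables:
            ax.plot(t, p[name], label=name)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("angle [deg]")
        ax.legend(loc="best", fontsize=8)
        return ax


def run_pipeline(
    config: PipelineConfig,
    trajectory_path: str | Path,
    detections_path: str | Path | None = None,
    *,
    layout: str = "canonical12",
    out_dir: str | Path | None = None,
    fps: float = 30.0,
    units: str = "meters",
) -> JointAngleResults:
    """End-to-end run: read inputs, track, correct, fit, optionally save."""
    try:
        model = JointAngleModel.from_csv(
            trajectory_path, layout,
            detections_path=detections_path, config=config,
            fps=fps, units=units,
        )
    except Exception as exc:
        raise PipelineError("io_formats", exc) from exc
    results = model.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
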