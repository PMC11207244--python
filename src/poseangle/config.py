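"""Pipeline configuration (YAML-loadable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .udeas import OptimizerConfig

__all__ = ["PipelineConfig", "DEFAULT_STATURES_CM", "load_config", "save_config"]

#: National-average statures used to convert pixel link lengths to cm.
DEFAULT_STATURES_CM = {"male": 175.0, "female": 160.0}


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    conf_threshold gates detector boxes; assumed_stature_cm converts pixel
    link lengths to centimeters (175 cm male / 160 cm female national
    averages); outlier_threshold_cm_per_frame is the link-length-derivative
    outlier threshold at 30 fps; median_window is the smoothing window
    (odd frames); optimizer holds the uDEAS settings.
    """

    conf_threshold: float = 0.5
    assumed_stature_cm: float = 175.0
    outlier_threshold_cm_per_frame: float = 10.0
    merge_gap: int = 2
    switch_link_count: int = 4
    median_window: int = 5
    max_track_gap: int = 5
    warm_start: bool = True
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    angle_bounds_deg: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if not 0 < self.conf_threshold <= 1:
            raise ValueError("conf_threshold must lie in (0, 1]")
        if self.median_window % 2 == 0 or self.median_window < 3:
            raise ValueError("median_window must be odd and >= 3")
        if self.assumed_stature_cm <= 0:
            raise ValueError("assumed_stature_cm must be positive")
        if isinstance(self.optimizer, dict):
            self.optimizer = OptimizerConfig(**self.optimizer)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def save_config(path: str | Path, cfg: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
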