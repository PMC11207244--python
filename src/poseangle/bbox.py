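"""Single-person region-of-interest selection and tracking.

Object detectors emit many boxes per frame (people, bicycles, furniture,
spurious duplicates).  The subject is picked in the first frame by filtering
on confidence and the person class and keeping the largest surviving box;
in later frames the person box maximizing confidence + IoU with the previous
selection is kept, so a high-confidence distractor elsewhere in the image
cannot steal the track.

Boxes are half-open pixel rectangles [x_min, x_max) x [y_min, y_max).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BoundingBox",
    "DetectionRecord",
    "RoiTrack",
    "TrackingError",
    "iou",
    "select_initial_roi",
    "track_roi",
    "track_sequence",
    "read_detections",
]

PERSON_LABEL = "person"


class TrackingError(RuntimeError):
    """No usable subject box."""


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError("box must have x_max >= x_min and y_max >= y_min")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class DetectionRecord:
    box: BoundingBox
    label: str
    conf: float

    def __post_init__(self):
        if not 0.0 <= self.conf <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class RoiTrack:
    """Per-frame selected box with its selection score (conf + IoU_max)."""

    boxes: list[BoundingBox] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    held_frames: list[int] = field(default_factory=list)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union; 0 when the union is empty."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _humans(detections, threshold=None):
    out = [d for d in detections if d.label == PERSON_LABEL]
    if threshold is not None:
        out = [d for d in out if d.conf >= threshold]
    return out


def select_initial_roi(
    detections: list[DetectionRecord],
    threshold: float = 0.5,
    *,
    floor: float = 0.05,
) -> BoundingBox:
    """Largest-area person box above the confidence threshold.

    When nothing survives, the threshold is halved and the selection retried
    until it drops below ``floor``; then a TrackingError is raised.  Area
    ties keep the first candidate in input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    t = threshold
    while True:
        candidates = _humans(detections, t)
        if candidates:
            return max(candidates, key=lambda d: d.box.area).box
        t /= 2.0
        if t < floor:
            raise TrackingError("no subject found: no person box above the floor threshold")


def track_roi(
    prev: BoundingBox, detections: list[DetectionRecord]
) -> tuple[BoundingBox, float]:
    """Person box maximizing conf + IoU with the previous selection.

    Returns (box, score).  Raises TrackingError when no person box exists
    (track lost; the caller decides the hold policy).
    """
    candidates = _humans(detections)
    if not candidates:
        raise TrackingError("track lost: no person detections this frame")
    best, best_score = None, -1.0
    for d in candidates:
        score = d.conf + iou(prev, d.box)
        if score > best_score:
            best, best_score = d.box, score
    return best, best_score


def track_sequence(
    detections_per_frame: list[list[DetectionRecord]],
    *,
    conf_threshold: float = 0.5,
    max_gap: int = 5,
) -> RoiTrack:
    """Select the subject in frame 0 and follow it through the sequence.

    Frames with no person detection hold the previous box for up to
    ``max_gap`` consecutive frames, after which the track is declared
    unrecoverable.
    """
    if not detections_per_frame:
        raise ValueError("need at least one frame of detections")
    track = RoiTrack()
    box = select_initial_roi(detections_per_frame[0], conf_threshold)
    track.boxes.append(box)
    track.scores.append(max(
        d.conf for d in _humans(detections_per_frame[0]) if d.box == box
    ) + 1.0 if _humans(detections_per_frame[0]) else 0.0)
    gap = 0
    for t, dets in enumerate(detections_per_frame[1:], start=1):
        try:
            box, score = track_roi(box, dets)
            gap = 0
        except TrackingError:
            gap += 1
            if gap > max_gap:
                raise TrackingError(
                    f"track lost for more than {max_gap} consecutive frames "
                    f"(frame {t})"
                ) from None
            score = 0.0
            track.held_frames.append(t)
        track.boxes.append(box)
        track.scores.append(score)
    return track


def read_detections(path: str | Path) -> list[list[DetectionRecord]]:
    """Load per-frame detection records from JSON.

    Format: a list (frames) of lists of
    ``{"label": str, "conf": float, "box": [x_min, y_min, x_max, y_max]}``.
    """
    raw = json.loads(Path(path).read_text())
    frames = []
    for fr in raw:
        frames.append([
            DetectionRecord(BoundingBox(*d["box"]), d["label"], d["conf"])
            for d in fr
        ])
    return frames
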