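"""Link-length-based outlier detection and correction.

Pose backends fail in characteristic ways: left/right landmark identity
switches, end-joint misdetections in occluded regions, and frame-to-frame
jitter.  True limb segments are rigid, so their lengths change smoothly
during motion; a corrupted frame shows a step change.  The detector monitors
the 10 major links (shoulder, pelvis, left/right upper arm, lower arm,
thigh, shin), differentiates each length series per frame, and flags frames
whose absolute length change exceeds a threshold.  Flagged frames merge into
segments; segments triggering many links at once are classed as left/right
switches (the whole body is affected), few links as local misdetections.

Correction removes the flagged frames and mean-interpolates them from the
last clean frame before and the first clean frame after the segment, then a
running median filter smooths residual jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Trajectory

__all__ = [
    "LINKS",
    "LINK_NAMES",
    "OutlierSegment",
    "OutlierMask",
    "link_lengths",
    "link_length_series",
    "normalize_to_cm",
    "detect_outliers",
    "correct_segment",
    "median_smooth",
    "correct_trajectory",
]

#: The 10 monitored links as (name, joint_a, joint_b).
LINKS: tuple[tuple[str, str, str], ...] = (
    ("shoulder", "l_shoulder", "r_shoulder"),
    ("pelvis", "l_hip", "r_hip"),
    ("l_upper_arm", "l_shoulder", "l_elbow"),
    ("r_upper_arm", "r_shoulder", "r_elbow"),
    ("l_lower_arm", "l_elbow", "l_wrist"),
    ("r_lower_arm", "r_elbow", "r_wrist"),
    ("l_thigh", "l_hip", "l_knee"),
    ("r_thigh", "r_hip", "r_knee"),
    ("l_shin", "l_knee", "l_ankle"),
    ("r_shin", "r_knee", "r_ankle"),
)
LINK_NAMES = tuple(l[0] for l in LINKS)

#: Joints moved when only the named link misbehaves (misdetection category).
_LINK_JOINTS = {name: (a, b) for name, a, b in LINKS}


@dataclass
class OutlierSegment:
    start: int            # first flagged frame
    stop: int             # last flagged frame (inclusive)
    links: tuple[str, ...]
    category: str         # "switch" | "misdetection"

    def __post_init__(self):
        if self.stop < self.start:
            raise ValueError("segment stop before start")

    @property
    def frames(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass
class OutlierMask:
    flags: np.ndarray                       # (n_frames,) bool
    segments: list[OutlierSegment] = field(default_factory=list)

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        prev_stop = -1
        for seg in self.segments:
            if seg.start <= prev_stop:
                raise ValueError("segments must be disjoint and ordered")
            if seg.stop >= self.flags.size:
                raise ValueError("segment outside frame range")
            prev_stop = seg.stop


def link_lengths(frame: dict[str, np.ndarray]) -> np.ndarray:
    """Euclidean lengths of the 10 links for one frame (input units)."""
    out = np.empty(len(LINKS))
    for i, (name, a, b) in enumerate(LINKS):
        if a not in frame or b not in frame:
            raise KeyError(f"link {name}: missing joint {a if a not in frame else b}")
        out[i] = float(np.linalg.norm(np.asarray(frame[a]) - np.asarray(frame[b])))
    return out


def link_length_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, diffs): per-frame link lengths and frame differences.

    lengths is (n_frames, 10); diffs is (n_frames - 1, 10).
    """
    lengths = np.empty((traj.n_frames, len(LINKS)))
    for i, (_, a, b) in enumerate(LINKS):
        lengths[:, i] = np.linalg.norm(traj.data[a] - traj.data[b], axis=1)
    return lengths, np.diff(lengths, axis=0)


def normalize_to_cm(
    lengths: np.ndarray, subject_pixel_height: float, stature_cm: float
) -> np.ndarray:
    """Convert pixel lengths to centimeters via an assumed subject stature.

    The default statures follow national averages: 175 cm for men and 160 cm
    for women.
    """
    if subject_pixel_height <= 0:
        raise ValueError("subject pixel height must be positive")
    if stature_cm <= 0:
        raise ValueError("stature must be positive")
    return np.asarray(lengths, dtype=float) * (stature_cm / subject_pixel_height)


def detect_outliers(
    diffs: np.ndarray,
    threshold_cm_per_frame: float = 10.0,
    *,
    merge_gap: int = 2,
    switch_link_count: int = 4,
) -> OutlierMask:
    """Flag frames whose link-length change exceeds the threshold.

    A step between frames t and t+1 flags frame t+1.  Flagged frames closer
    than ``merge_gap`` merge into one segment.  Segments where at least
    ``switch_link_count`` links trigger simultaneously on some frame are
    categorized as left/right switches; others as misdetections.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_frames = diffs.shape[0] + 1
    hits = np.abs(diffs) > threshold_cm_per_frame     # (n_frames-1, n_links)
    flags = np.zeros(n_frames, dtype=bool)
    flags[1:] = hits.any(axis=1)
    segments: list[OutlierSegment] = []
    flagged = np.flatnonzero(flags)
    if flagged.size:
        groups = [[flagged[0]]]
        for f in flagged[1:]:
            if f - groups[-1][-1] <= merge_gap:
                groups[-1].append(f)
            else:
                groups.append([f])
        for grp in groups:
            start, stop = int(grp[0]), int(grp[-1])
            span = hits[start - 1:stop]               # diff rows of this segment
            links = tuple(
                LINK_NAMES[i] for i in np.flatnonzero(span.any(axis=0))
            )
            simultaneous = int(span.sum(axis=1).max()) if span.size else 0
            category = "switch" if simultaneous >= switch_link_count else "misdetection"
            segments.append(OutlierSegment(start, stop, links, category))
            flags[start:stop + 1] = True  # include merged-gap interior frames
    return OutlierMask(flags, segments)


def correct_segment(
    traj: Trajectory,
    segment: OutlierSegment,
    *,
    joints: tuple[str, ...] | None = None,
) -> Trajectory:
    """Mean-interpolate the segment's frames from its clean neighbors.

    Every affected joint coordinate inside [start, stop] becomes the average
    of the last frame before the segment and the first frame after it.  At a
    sequence boundary the single available neighbor is replicated.
    ``joints=None`` corrects all joints.
    """
    out = traj.copy()
    n = traj.n_frames
    before = segment.start - 1
    after = segment.stop + 1
    if before < 0 and after >= n:
        raise ValueError("segment spans the whole sequence; nothing to interpolate from")
    targets = traj.data.keys() if joints is None else joints
    for j in targets:
        arr = out.data[j]
        if before < 0:
            fill = arr[after]
        elif after >= n:
            fill = arr[before]
        else:
            fill = 0.5 * (arr[before] + arr[after])
        arr[segment.start:segment.stop + 1] = fill
    return out


def median_smooth(traj: Trajectory, window: int = 5) -> Trajectory:
    """Per-coordinate running median; edges use a shrunken window."""
    if window % 2 == 0 or window < 3:
        raise ValueError("median window must be odd and >= 3")
    h = window // 2
    out = traj.copy()
    n = traj.n_frames
    for j, arr in traj.data.items():
        sm = np.empty_like(arr)
        for i in range(n):
            sm[i] = np.median(arr[max(0, i - h):min(n, i + h + 1)], axis=0)
        out.data[j] = sm
    return out


def correct_trajectory(
    traj: Trajectory,
    *,
    threshold_cm_per_frame: float = 10.0,
    fps_reference: float = 30.0,
    merge_gap: int = 2,
    switch_link_count: int = 4,
    median_window: int = 5,
    subject_pixel_height: float | None = None,
    stature_cm: float = 175.0,
    apply_median: bool = True,
) -> tuple[Trajectory, OutlierMask]:
    """Full correction pass: detect, interpolate, median-smooth.

    The threshold is stated per frame at ``fps_reference``; at other frame
    rates it scales inversely with fps (the same physical speed produces a
    smaller per-frame step at a higher rate).  Pixel-unit trajectories are
    normalized to cm through the subject's pixel height and assumed stature
    before thresholding.  Switch segments correct every joint; misdetection
    segments only the joints of the triggering links.
    """
    lengths, diffs = link_length_series(traj)
    if traj.units == "pixels":
        if subject_pixel_height is None:
            ys = np.concatenate([traj.data[j][:, 1] for j in traj.data])
            subject_pixel_height = float(np.ptp(ys))
        diffs_cm = normalize_to_cm(diffs, subject_pixel_height, stature_cm)
    else:
        diffs_cm = diffs * 100.0  # meters -> cm
    threshold = threshold_cm_per_frame * (fps_reference / traj.fps)
    mask = detect_outliers(
        diffs_cm, threshold,
        merge_gap=merge_gap, switch_link_count=switch_link_count,
    )
    corrected = traj.copy()
    for seg in mask.segments:
        if seg.category == "switch":
            joints = None
        else:
            names = {j for l in seg.links for j in _LINK_JOINTS[l]}
            joints = tuple(sorted(names))
        corrected = correct_segment(corrected, seg, joints=joints)
    if apply_median:
        corrected = median_smooth(corrected, median_window)
    return corrected, mask


def mask_report(mask: OutlierMask) -> dict:
    """JSON-serializable outlier report."""
    return {
        "n_frames": int(mask.flags.size),
        "n_flagged": int(mask.flags.sum()),
        "segments": [
            {
                "start": seg.start,
                "stop": seg.stop,
                "links": list(seg.links),
                "category": seg.category,
            }
            for seg in mask.segments
        ],
    }
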