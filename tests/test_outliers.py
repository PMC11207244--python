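"""Link-length outlier detection, mean interpolation and median smoothing."""

import numpy as np
import pytest

from poseangle import CANONICAL_JOINTS
from poseangle.io import Trajectory
from poseangle.outliers import (
    LINK_NAMES,
    LINKS,
    OutlierMask,
    OutlierSegment,
    correct_segment,
    correct_trajectory,
    detect_outliers,
    link_length_series,
    link_lengths,
    median_smooth,
    normalize_to_cm,
)
from poseangle.synthetic import (
    CorruptionSpec,
    MisdetectionEvent,
    SwitchEvent,
    corrupt,
    default_script,
    generate_motion,
)


def frame_of(**kw):
    f = {j: np.zeros(3) for j in CANONICAL_JOINTS}
    f.update({k: np.asarray(v, float) for k, v in kw.items()})
    return f


class TestLinkLengths:
    def test_ten_links(self):
        assert len(LINKS) == 10

    def test_3_4_5_triangle(self):
        f = frame_of(l_shoulder=(0, 0, 0), l_elbow=(0.3, 0, 0.4))
        out = link_lengths(f)
        assert out[LINK_NAMES.index("l_upper_arm")] == pytest.approx(0.5)

    def test_coincident_endpoints_zero(self):
        assert np.allclose(link_lengths(frame_of()), 0.0)

    def test_matches_independent_distance_formula(self, rng):
        f = {j: rng.normal(size=3) for j in CANONICAL_JOINTS}
        got = link_lengths(f)
        for i, (_, a, b) in enumerate(LINKS):
            dx, dy, dz = (f[a][k] - f[b][k] for k in range(3))
            assert got[i] == pytest.approx((dx**2 + dy**2 + dz**2) ** 0.5, abs=1e-12)

    def test_missing_joint_names_link(self):
        f = frame_of()
        del f["r_wrist"]
        with pytest.raises(KeyError, match="r_lower_arm"):
            link_lengths(f)


class TestNormalize:
    def test_stature_scale(self):
        # 175 cm subject spanning 350 px: scale 0.5; a 60 px link is 30 cm
        assert normalize_to_cm(np.array([60.0]), 350.0, 175.0)[0] == pytest.approx(30.0)

    def test_scale_invariance(self):
        a = normalize_to_cm(np.array([60.0]), 350.0, 175.0)
        b = normalize_to_cm(np.array([120.0]), 700.0, 175.0)
        assert np.allclose(a, b)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_cm(np.array([1.0]), 0.0, 175.0)


class TestDetect:
    def test_constant_lengths_clean(self):
        diffs = np.zeros((20, 10))
        mask = detect_outliers(diffs, 10.0)
        assert not mask.flags.any()
        assert mask.segments == []

    def test_single_jump_flagged(self):
        diffs = np.zeros((20, 10))
        diffs[7, 3] = 30.0  # 30 cm step between frames 7 and 8
        mask = detect_outliers(diffs, 10.0)
        assert list(np.flatnonzero(mask.flags)) == [8]
        (seg,) = mask.segments
        assert (seg.start, seg.stop) == (8, 8)
        assert seg.links == (LINK_NAMES[3],)
        assert seg.category == "misdetection"

    def test_linear_drift_not_flagged(self):
        diffs = np.full((50, 10), 0.5)
        assert not detect_outliers(diffs, 10.0).flags.any()

    def test_many_links_simultaneously_is_switch(self):
        diffs = np.zeros((10, 10))
        diffs[4, :6] = 25.0
        (seg,) = detect_outliers(diffs, 10.0).segments
        assert seg.category == "switch"
        assert len(seg.links) == 6

    def test_nearby_flags_merge(self):
        diffs = np.zeros((20, 10))
        diffs[5, 0] = 20.0
        diffs[7, 0] = -20.0
        mask = detect_outliers(diffs, 10.0, merge_gap=2)
        (seg,) = mask.segments
        assert (seg.start, seg.stop) == (6, 8)


def ramp_traj(n=9, lo=1.0, hi=3.0):
    data = {j: np.zeros((n, 3)) for j in CANONICAL_JOINTS}
    for j in data:
        data[j][:, 0] = np.linspace(lo, hi, n)
    return Trajectory(data)


class TestCorrectSegment:
    def test_mean_of_neighbors(self):
        t = ramp_traj(7)
        t.data["l_wrist"][2:5, 0] = 99.0
        seg = OutlierSegment(2, 4, ("l_lower_arm",), "misdetection")
        out = correct_segment(t, seg, joints=("l_wrist",))
        expect = 0.5 * (t.data["l_wrist"][1, 0] + t.data["l_wrist"][5, 0])
        assert np.allclose(out.data["l_wrist"][2:5, 0], expect)
        # untouched joints and frames unchanged
        assert np.allclose(out.data["l_wrist"][[0, 1, 5, 6]],
                           t.data["l_wrist"][[0, 1, 5, 6]])
        assert np.allclose(out.data["r_wrist"], t.data["r_wrist"])

    def test_explicit_values(self):
        data = {j: np.zeros((5, 3)) for j in CANONICAL_JOINTS}
        data["l_knee"][:, 1] = [1.0, 1.0, 9.0, 9.0, 3.0]
        t = Trajectory(data)
        out = correct_segment(t, OutlierSegment(2, 3, (), "switch"))
        assert np.allclose(out.data["l_knee"][2:4, 1], 2.0)  # mean of 1 and 3

    def test_segment_at_start_replicates_post_neighbor(self):
        t = ramp_traj(5)
        out = correct_segment(t, OutlierSegment(0, 1, (), "switch"))
        assert np.allclose(out.data["l_hip"][0], t.data["l_hip"][2])
        assert np.allclose(out.data["l_hip"][1], t.data["l_hip"][2])

    def test_segment_at_end_replicates_pre_neighbor(self):
        t = ramp_traj(5)
        out = correct_segment(t, OutlierSegment(3, 4, (), "switch"))
        assert np.allclose(out.data["l_hip"][3:], t.data["l_hip"][2])

    def test_whole_sequence_segment_rejected(self):
        t = ramp_traj(4)
        with pytest.raises(ValueError):
            correct_segment(t, OutlierSegment(0, 3, (), "switch"))


class TestMedianSmooth:
    def sort_oracle(self, x, window):
        h = window // 2
        out = []
        for i in range(len(x)):
            w = sorted(x[max(0, i - h):min(len(x), i + h + 1)])
            n = len(w)
            out.append(w[n // 2] if n % 2 else 0.5 * (w[n // 2 - 1] + w[n // 2]))
        return np.array(out)

    def test_constant_unchanged(self):
        data = {j: np.full((10, 3), 2.5) for j in CANONICAL_JOINTS}
        out = median_smooth(Trajectory(data), 5)
        assert np.allclose(out.data["l_ankle"], 2.5)

    def test_spike_removed(self):
        data = {j: np.ones((11, 3)) for j in CANONICAL_JOINTS}
        data["r_elbow"][5] = 50.0
        out = median_smooth(Trajectory(data), 5)
        assert np.allclose(out.data["r_elbow"], 1.0)

    def test_matches_sort_based_oracle(self, rng):
        data = {j: rng.normal(size=(25, 3)) for j in CANONICAL_JOINTS}
        t = Trajectory(data)
        out = median_smooth(t, 5)
        for j in ("l_wrist", "r_knee"):
            for k in range(3):
                oracle = self.sort_oracle(t.data[j][:, k], 5)
                assert np.allclose(out.data[j][:, k], oracle)

    def test_monotone_series_interior_unchanged(self):
        t = ramp_traj(15)
        out = median_smooth(t, 5)
        assert np.allclose(out.data["l_hip"][2:-2], t.data["l_hip"][2:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(ramp_traj(), 4)


class TestCorrectTrajectory:
    def test_clean_motion_unflagged(self):
        _, traj = generate_motion(default_script("rowing", duration_frames=40))
        corrected, mask = correct_trajectory(traj)
        assert not mask.flags.any()
        smoothed = median_smooth(traj, 5)
        for j in corrected.data:
            assert np.allclose(corrected.data[j], smoothed.data[j])

    def test_injected_partial_switch_detected_and_repaired(self):
        # frames chosen where the arm swing is strongly asymmetric, so
        # swapping the wrists breaks the lower-arm links hard
        _, traj = generate_motion(default_script("arm_leg", duration_frames=60))
        spec = CorruptionSpec(switches=[SwitchEvent(20, 21, pairs=("wrist",))])
        bad, truth = corrupt(traj, spec)
        corrected, mask = correct_trajectory(bad)
        assert mask.flags[20:23].any()
        _, diffs = link_length_series(corrected)
        assert np.abs(diffs * 100).max() < 10.0  # post-correction below threshold

    def test_wrist_teleport_triggers_lower_arm_link(self):
        _, traj = generate_motion(default_script("rowing", duration_frames=50))
        # displace along the lower-arm axis so the length jump equals 0.6 m
        v = traj.data["l_wrist"][20] - traj.data["l_elbow"][20]
        d = tuple(0.6 * v / np.linalg.norm(v))
        spec = CorruptionSpec(misdetections=[
            MisdetectionEvent("l_wrist", 20, 21, displacement=d)
        ])
        bad, _ = corrupt(traj, spec)
        corrected, mask = correct_trajectory(bad)
        assert len(mask.segments) >= 1
        assert any("l_lower_arm" in seg.links for seg in mask.segments)

    def test_non_flagged_frames_only_median_filtered(self):
        _, traj = generate_motion(default_script("rowing", duration_frames=60))
        spec = CorruptionSpec(misdetections=[
            MisdetectionEvent("r_wrist", 25, 26, displacement=(0.6, 0, 0))
        ])
        bad, _ = corrupt(traj, spec)
        corrected, mask = correct_trajectory(bad, apply_median=False)
        clean = ~mask.flags
        for j in corrected.data:
            assert np.allclose(corrected.data[j][clean], bad.data[j][clean])

    def test_idempotent_on_clean_data(self):
        _, traj = generate_motion(default_script("back_chest", duration_frames=40))
        once, m1 = correct_trajectory(traj)
        twice, m2 = correct_trajectory(once)
        assert not m1.flags.any() and not m2.flags.any()
        # median filter is idempotent away from the shrinking-window edges
        for j in once.data:
            assert np.allclose(twice.data[j][3:-3], once.data[j][3:-3], atol=1e-9)


class TestDetectionQuality:
    def test_recall_and_precision_on_strong_corruptions(self, rng):
        """Segment-level recall >= 0.9, precision >= 0.8 for jumps >= 3x threshold."""
        tp = fp = fn = 0
        for trial in range(12):
            script = default_script(
                ["rowing", "back_chest", "arm_leg"][trial % 3], duration_frames=80
            )
            _, traj = generate_motion(script)
            start = int(rng.integers(10, 60))
            joint = ["l_wrist", "r_wrist", "l_ankle", "r_ankle"][trial % 4]
            parent = {"l_wrist": "l_elbow", "r_wrist": "r_elbow",
                      "l_ankle": "l_knee", "r_ankle": "r_knee"}[joint]
            # displace along the link axis: induced length jump is exactly
            # 60 cm >> 3 * the 10 cm/frame threshold
            v = traj.data[joint][start] - traj.data[parent][start]
            disp = tuple(0.6 * v / np.linalg.norm(v))
            spec = CorruptionSpec(misdetections=[
                MisdetectionEvent(joint, start, start + int(rng.integers(0, 3)),
                                  displacement=disp)
            ], jitter_sigma_m=0.003, seed=int(rng.integers(2**31)))
            bad, truth = corrupt(traj, spec)
            _, mask = correct_trajectory(bad)
            true_segs = [(s.start, s.stop) for s in truth.segments]
            det_segs = [(s.start, s.stop) for s in mask.segments]

            def overlaps(a, b):
                return a[0] <= b[1] + 1 and b[0] <= a[1] + 1

            for ts in true_segs:
                if any(overlaps(ts, ds) for ds in det_segs):
                    tp += 1
                else:
                    fn += 1
            for ds in det_segs:
                if not any(overlaps(ds, ts) for ts in true_segs):
                    fp += 1
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.9
        assert precision >= 0.8


def test_outlier_mask_validation():
    with pytest.raises(ValueError):
        OutlierMask(np.zeros(5, bool), [OutlierSegment(1, 9, (), "switch")])
    with pytest.raises(ValueError):
        OutlierMask(np.zeros(9, bool), [
            OutlierSegment(1, 4, (), "switch"), OutlierSegment(3, 6, (), "switch"),
        ])
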