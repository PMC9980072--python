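"""Postural features, the heuristic bout detector, and interval agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groomens import (
    DEFAULT_THRESHOLDS,
    GroomingBouts,
    HeuristicThresholds,
    Pose3DTrack,
    compute_postural_features,
    detect_grooming,
    jaccard_agreement,
    merge_close_bouts,
)
from groomens.grooming import KEYPOINT_NAMES, PosturalFeatures


def _track_from_points(points: dict, n_frames: int = 1, rate: float = 10.0,
                       confidence=None) -> Pose3DTrack:
    coords = np.zeros((n_frames, len(KEYPOINT_NAMES), 3))
    for k, name in enumerate(KEYPOINT_NAMES):
        coords[:, k, :] = points.get(name, (0.0, 0.0, 0.0))
    return Pose3DTrack(
        frame_rate_hz=rate,
        frames=np.arange(n_frames),
        keypoints=tuple(KEYPOINT_NAMES),
        coords=coords,
        confidence=confidence,
    )


def _features_from_flags(flags, rate=10.0) -> PosturalFeatures:
    """Features crafted so the grooming predicate equals the given flags."""
    flags = np.asarray(flags, dtype=bool)
    n = len(flags)
    hi, lo = 5.0, 0.0
    return PosturalFeatures(
        frame_rate_hz=rate,
        snout_height=np.where(flags, hi, lo),
        eyes_mid_to_hind_mid=np.where(flags, 4.0, 9.0),
        paws_mid_to_snout=np.where(flags, 0.5, 5.0),
        paws_mid_to_eyes_mid=np.where(flags, 0.5, 5.0),
        paws_mid_height=np.where(flags, 4.0, 0.0),
        body_speed=np.zeros(n),
    )


class TestPosturalFeatures:
    def test_paws_to_snout_distance(self):
        t = _track_from_points(
            {"paw_L": (0, 0, 0), "paw_R": (2, 0, 0), "snout": (1, 0, 4)}
        )
        f = compute_postural_features(t)
        assert f.paws_mid_to_snout[0] == pytest.approx(4.0)

    def test_eyes_to_hind_distance(self):
        t = _track_from_points(
            {
                "eye_L": (0, 0, 3), "eye_R": (2, 0, 3),
                "hind_L": (0, 6, 0), "hind_R": (2, 6, 0),
            }
        )
        f = compute_postural_features(t)
        assert f.eyes_mid_to_hind_mid[0] == pytest.approx(np.sqrt(45), abs=1e-6)

    def test_stationary_track_has_zero_speed(self):
        t = _track_from_points({"snout": (1, 1, 1)}, n_frames=20)
        f = compute_postural_features(t)
        np.testing.assert_allclose(f.body_speed, 0.0)

    def test_missing_keypoint_error_names_it(self):
        coords = np.zeros((3, 3, 3))
        t = Pose3DTrack(10.0, np.arange(3), ("snout", "paw_L", "paw_R"), coords)
        with pytest.raises(KeyError, match="eye_L"):
            compute_postural_features(t)

    def test_low_confidence_keypoint_fails_predicates(self):
        groom_points = {
            "snout": (0.5, 0, 5.0), "eye_L": (0.45, 0.3, 4.6),
            "eye_R": (0.45, -0.3, 4.6), "paw_L": (0.5, 0.25, 4.3),
            "paw_R": (0.5, -0.25, 4.3), "hind_L": (-0.5, 0.4, 0.1),
            "hind_R": (-0.5, -0.4, 0.1),
        }
        conf = np.ones((1, len(KEYPOINT_NAMES)))
        t = _track_from_points(groom_points, confidence=conf)
        from groomens.grooming import grooming_frame_flags

        assert grooming_frame_flags(compute_postural_features(t)).all()
        conf2 = conf.copy()
        conf2[0, KEYPOINT_NAMES.index("snout")] = 0.3
        t2 = _track_from_points(groom_points, confidence=conf2)
        assert not grooming_frame_flags(compute_postural_features(t2)).any()


class TestDetect:
    def test_runs_within_merge_window_become_one_bout(self):
        rate = 10.0
        flags = np.zeros(200, dtype=bool)
        flags[100:110] = True  # [10.0, 11.0) s
        flags[118:135] = True  # [11.8, 13.5) s; gap 0.8 s < 1.2 s
        bouts = detect_grooming(_features_from_flags(flags, rate))
        np.testing.assert_allclose(bouts.intervals, [[10.0, 13.5]])

    def test_short_bout_discarded(self):
        flags = np.zeros(100, dtype=bool)
        flags[10:25] = True  # 1.5 s < 2 s
        assert len(detect_grooming(_features_from_flags(flags, 10.0))) == 0

    def test_no_flags_no_bouts(self):
        assert len(detect_grooming(_features_from_flags(np.zeros(50, bool)))) == 0

    def test_gap_at_least_merge_window_not_merged(self):
        rate = 10.0
        flags = np.zeros(400, dtype=bool)
        flags[100:130] = True  # [10, 13)
        flags[143:180] = True  # [14.3, 18); gap 1.3 s >= 1.2 s
        bouts = detect_grooming(_features_from_flags(flags, rate))
        assert len(bouts) == 2

    @given(st.lists(st.booleans(), min_size=0, max_size=300))
    @settings(max_examples=60, deadline=None)
    def test_output_invariants_for_arbitrary_flags(self, flag_list):
        bouts = detect_grooming(_features_from_flags(np.array(flag_list, bool)))
        iv = bouts.intervals
        assert np.all(iv[:, 1] > iv[:, 0])
        assert np.all(iv[:, 1] - iv[:, 0] >= DEFAULT_THRESHOLDS.min_bout_s - 1e-9)
        if len(iv) > 1:
            gaps = iv[1:, 0] - iv[:-1, 1]
            assert np.all(gaps >= DEFAULT_THRESHOLDS.merge_window_s - 1e-9)


class TestMerge:
    def test_gap_below_threshold_merged(self):
        b = GroomingBouts.from_pairs([(0, 10), (12.5, 20)])
        np.testing.assert_allclose(merge_close_bouts(b).intervals, [[0, 20]])

    def test_gap_at_or_above_threshold_kept(self):
        b = GroomingBouts.from_pairs([(0, 10), (13.5, 20)])
        assert len(merge_close_bouts(b)) == 2
        b2 = GroomingBouts.from_pairs([(0, 10), (13.0, 20)])
        assert len(merge_close_bouts(b2)) == 2  # gap exactly 3 s: strict rule

    def test_empty(self):
        assert len(merge_close_bouts(GroomingBouts.empty())) == 0

    @given(
        st.lists(
            st.tuples(st.floats(0, 500), st.floats(0.1, 30)),
            min_size=0, max_size=20,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent(self, raw):
        starts = np.sort([s for s, _ in raw])
        iv, t = [], 0.0
        for (s, d) in zip(starts, [d for _, d in raw]):
            a = max(s, t + 0.01)
            iv.append((a, a + d))
            t = a + d
        b = GroomingBouts.from_pairs(iv)
        once = merge_close_bouts(b)
        twice = merge_close_bouts(once)
        np.testing.assert_allclose(once.intervals, twice.intervals)


class TestJaccard:
    def test_examples(self):
        a = GroomingBouts.from_pairs([(0, 10)])
        b = GroomingBouts.from_pairs([(5, 15)])
        assert jaccard_agreement(a, b, 100) == pytest.approx(5 / 15)
        assert jaccard_agreement(a, a, 100) == 1.0
        c = GroomingBouts.from_pairs([(50, 60)])
        assert jaccard_agreement(a, c, 100) == 0.0
        assert jaccard_agreement(GroomingBouts.empty(), GroomingBouts.empty(), 10) == 1.0

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_per_frame_iou_and_symmetry(self, data):
        # brute-force oracle: per-frame set IoU at 100 fps resolution
        def random_bouts(d):
            n = d.draw(st.integers(0, 5))
            edges = sorted(
                d.draw(
                    st.lists(
                        st.integers(0, 1000), min_size=2 * n, max_size=2 * n,
                        unique=True,
                    )
                )
            )
            return GroomingBouts.from_pairs(
                [(edges[2 * i] / 100, edges[2 * i + 1] / 100) for i in range(n)]
            )

        a, b = random_bouts(data), random_bouts(data)
        total = 10.0
        assert jaccard_agreement(a, b, total) == pytest.approx(
            jaccard_agreement(b, a, total)
        )
        frames = (np.arange(1000) + 0.5) / 100.0

        def member(bouts):
            out = np.zeros(len(frames), bool)
            for s, e in bouts:
                out |= (frames >= s) & (frames < e)
            return out

        fa, fb = member(a), member(b)
        union = (fa | fb).sum()
        oracle = 1.0 if union == 0 else (fa & fb).sum() / union
        assert jaccard_agreement(a, b, total) == pytest.approx(oracle, abs=1e-9)


def test_threshold_validation():
    with pytest.raises(ValueError):
        HeuristicThresholds(merge_window_s=0.0)
    with pytest.raises(ValueError):
        HeuristicThresholds(min_bout_s=-1.0)
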