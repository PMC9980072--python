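"""Grooming-bout detection from 3D keypoint tracks.

A mouse grooming bout is detected purely posturally: frames where the animal
is rearing (snout high, body compressed) with its forepaws held near the
snout are flagged, flagged runs separated by short gaps are merged, and
candidate bouts that are too brief are discarded.  The heuristic thresholds
are arena-specific, dimensionless config values; the defaults here are
calibrated to the geometry of the synthetic pose generator in
:mod:`groomens.synthetic`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    GroomingBouts,
    interval_intersection_length,
    interval_union_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KEYPOINT_NAMES",
    "Pose3DTrack",
    "PosturalFeatures",
    "HeuristicThresholds",
    "DEFAULT_THRESHOLDS",
    "compute_postural_features",
    "detect_grooming",
    "jaccard_agreement",
    "merge_close_bouts",
]

#: The 15 tracked keypoints: snout, both paws, wrists, elbows, shoulders,
#: eyes, ears, and hind paws.
KEYPOINT_NAMES = (
    "snout",
    "eye_L",
    "eye_R",
    "ear_L",
    "ear_R",
    "shoulder_L",
    "shoulder_R",
    "elbow_L",
    "elbow_R",
    "wrist_L",
    "wrist_R",
    "paw_L",
    "paw_R",
    "hind_L",
    "hind_R",
)

#: Keypoints the postural features cannot do without.
REQUIRED_KEYPOINTS = ("snout", "paw_L", "paw_R", "eye_L", "eye_R", "hind_L", "hind_R")

#: Keypoint confidence below this is treated as missing (features become NaN
#: and conservatively fail every grooming predicate).
CONFIDENCE_CUTOFF = 0.6


@dataclass
class Pose3DTrack:
    """3D keypoint coordinates per frame.

    ``coords`` has shape (n_frames, n_keypoints, 3); ``keypoints`` names the
    second axis.  ``confidence`` is optional, shape (n_frames, n_keypoints),
    values in [0, 1].  ``frames`` are strictly increasing frame indices; frame
    ``f`` spans the time interval ``[f/rate, (f+1)/rate)``.
    """

    frame_rate_hz: float
    frames: np.ndarray
    keypoints: tuple
    coords: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.coords = np.asarray(self.coords)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.coords.shape != (len(self.frames), len(self.keypoints), 3):
            raise ValueError("coords must have shape (n_frames, n_keypoints, 3)")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def get(self, name: str) -> np.ndarray:
        """(n_frames, 3) coordinates of one named keypoint; NaN where missing."""
        try:
            k = self.keypoints.index(name)
        except ValueError:
            raise KeyError(f"required keypoint {name!r} is not in the track") from None
        xyz = self.coords[:, k, :].astype(float, copy=True)
        if self.confidence is not None:
            xyz[self.confidence[:, k] < CONFIDENCE_CUTOFF] = np.nan
        return xyz


@dataclass
class PosturalFeatures:
    """Per-frame scalar features of the 3D posture (one row per frame)."""

    frame_rate_hz: float
    snout_height: np.ndarray
    eyes_mid_to_hind_mid: np.ndarray
    paws_mid_to_snout: np.ndarray
    paws_mid_to_eyes_mid: np.ndarray
    paws_mid_height: np.ndarray
    body_speed: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.snout_height)


@dataclass(frozen=True)
class HeuristicThresholds:
    """Postural thresholds for the per-frame grooming predicate.

    Rearing requires ``snout_height > min_snout_height`` and
    ``eyes_mid_to_hind_mid < max_eyes_hind_dist`` (body compressed over the
    haunches); paws-near-head requires the paw midpoint to be close to the
    snout and eyes and held high.  ``max_speed`` adds an optional low-speed
    predicate.  Distances are in arena units (the triangulated coordinate
    frame carries no stated physical unit).
    """

    min_snout_height: float = 3.5
    max_eyes_hind_dist: float = 5.5
    max_paws_snout_dist: float = 1.5
    max_paws_eyes_dist: float = 1.5
    min_paws_height: float = 2.0
    max_speed: float | None = None
    merge_window_s: float = 1.2
    min_bout_s: float = 2.0

    def __post_init__(self) -> None:
        if self.merge_window_s <= 0:
            raise ValueError("merge_window_s must be positive")
        if self.min_bout_s < 0:
            raise ValueError("min_bout_s must be non-negative")

    def with_(self, **kw) -> "HeuristicThresholds":
        return replace(self, **kw)


DEFAULT_THRESHOLDS = HeuristicThresholds()


def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (a + b)


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def compute_postural_features(
    track: Pose3DTrack, speed_smooth_window_s: float = 0.2
) -> PosturalFeatures:
    """Compute the per-frame postural features the grooming heuristic uses.

    Midpoints are coordinate-wise means of the two named keypoints and
    distances are 3D Euclidean.  ``body_speed`` is the frame-to-frame
    displacement of the eyes midpoint times the frame rate, smoothed with a
    centred moving average of width ``speed_smooth_window_s``.  Features of
    frames with a missing (low-confidence) keypoint are NaN and later fail
    the grooming predicate.
    """
    for name in REQUIRED_KEYPOINTS:
        if name not in track.keypoints:
            raise KeyError(f"required keypoint {name!r} is not in the track")

    snout = track.get("snout")
    eyes_mid = _midpoint(track.get("eye_L"), track.get("eye_R"))
    paws_mid = _midpoint(track.get("paw_L"), track.get("paw_R"))
    hind_mid = _midpoint(track.get("hind_L"), track.get("hind_R"))

    n = track.n_frames
    speed = np.zeros(n)
    if n > 1:
        step = _dist(eyes_mid[1:], eyes_mid[:-1]) * track.frame_rate_hz
        # attribute each step to its later frame; frame 0 copies frame 1
        speed[1:] = step
        speed[0] = step[0]
        win = max(1, int(round(speed_smooth_window_s * track.frame_rate_hz)))
        if win > 1:
            kernel = np.ones(win) / win
            pad = np.pad(speed, (win // 2, win - 1 - win // 2), mode="edge")
            speed = np.convolve(pad, kernel, mode="valid")

    return PosturalFeatures(
        frame_rate_hz=track.frame_rate_hz,
        snout_height=snout[:, 2],
        eyes_mid_to_hind_mid=_dist(eyes_mid, hind_mid),
        paws_mid_to_snout=_dist(paws_mid, snout),
        paws_mid_to_eyes_mid=_dist(paws_mid, eyes_mid),
        paws_mid_height=paws_mid[:, 2],
        body_speed=speed,
    )


def grooming_frame_flags(
    feat: PosturalFeatures, thr: HeuristicThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Boolean per-frame grooming predicate (conjunction of all heuristics).

    NaN features compare False, so frames with missing keypoints are never
    flagged as grooming.
    """
    with np.errstate(invalid="ignore"):
        flags = (
            (feat.snout_height > thr.min_snout_height)
            & (feat.eyes_mid_to_hind_mid < thr.max_eyes_hind_dist)
            & (feat.paws_mid_to_snout < thr.max_paws_snout_dist)
            & (feat.paws_mid_to_eyes_mid < thr.max_paws_eyes_dist)
            & (feat.paws_mid_height > thr.min_paws_height)
        )
        if thr.max_speed is not None:
            flags &= feat.body_speed < thr.max_speed
    return flags


def _runs(flags: np.ndarray) -> np.ndarray:
    """Contiguous True runs as (start_frame, stop_frame_exclusive) pairs."""
    if not flags.any():
        return np.empty((0, 2), dtype=int)
    edges = np.diff(flags.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if flags[0]:
        starts = np.r_[0, starts]
    if flags[-1]:
        stops = np.r_[stops, len(flags)]
    return np.column_stack([starts, stops])


def detect_grooming(
    feat: PosturalFeatures, thr: HeuristicThresholds = DEFAULT_THRESHOLDS
) -> GroomingBouts:
    """Turn per-frame postural flags into grooming bouts.

    Flagged runs whose gaps are shorter than ``thr.merge_window_s`` (strictly)
    are merged, then merged bouts shorter than ``thr.min_bout_s`` are
    discarded.  Output intervals are half-open, in seconds: a run of frames
    ``f0..f1`` becomes ``[f0/rate, (f1+1)/rate)``.
    """
    if feat.n_frames == 0:
        return GroomingBouts.empty()
    flags = grooming_frame_flags(feat, thr)
    runs = _runs(flags)
    if not len(runs):
        return GroomingBouts.empty()
    rate = feat.frame_rate_hz
    intervals = runs.astype(float) / rate  # stop is exclusive: (f1+1)/rate already
    merged = _merge_gaps(intervals, thr.merge_window_s)
    keep = (merged[:, 1] - merged[:, 0]) >= thr.min_bout_s
    return GroomingBouts(merged[keep])


def _merge_gaps(intervals: np.ndarray, max_gap_s: float) -> np.ndarray:
    """Single left-to-right pass closing gaps strictly smaller than max_gap_s."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] < max_gap_s:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def merge_close_bouts(bouts: GroomingBouts, max_gap_s: float = 3.0) -> GroomingBouts:
    """Merge bouts separated by a gap strictly shorter than ``max_gap_s``.

    Mirrors the annotation rule that two grooming bouts less than 3 s apart
    count as a single bout.  Idempotent.
    """
    return GroomingBouts(_merge_gaps(bouts.intervals, max_gap_s))


def jaccard_agreement(a: GroomingBouts, b: GroomingBouts, total_duration_s: float) -> float:
    """Temporal Jaccard index (intersection over union) of two bout sets.

    Returns 1.0 when both annotations are empty (both agree there is no
    grooming; logged as the degenerate convention).
    """
    for bouts in (a, b):
        iv = bouts.intervals
        if len(iv) and (iv[0, 0] < 0 or iv[-1, 1] > total_duration_s + 1e-9):
            raise ValueError("bout intervals must lie within [0, total_duration_s]")
    union = interval_union_length(a, b)
    if union == 0.0:
        logger.debug("jaccard_agreement: both annotations empty, returning 1.0")
        return 1.0
    return interval_intersection_length(a, b) / union
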