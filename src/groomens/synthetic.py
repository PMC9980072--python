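"""Synthetic grooming sessions with planted ground truth.

Generates the three ingredients of a session — a grooming bout schedule, a
population of SPN/FSI spike trains with planted co-active ensembles, and a
125-fps 3D pose track whose posture is grooming-like exactly during bouts —
so that every downstream stage of the pipeline can be exercised against a
known answer.

The defaults emulate the statistics of spontaneous mouse grooming in a 2 h
session: about 4.1% of the session spent grooming, mean bout duration
12.4 s, mean inter-bout interval 4.3 min.  Bout durations are log-normal and
inter-bout gaps exponential; both families are right-skewed, matching the
shape of empirical bout-duration and gap histograms, while only their means
are pinned by the emulation targets.

Ensemble co-activity is modelled as (a) a shared active epoch per ensemble,
during which every member multiplies its baseline rate by the response
profile's gain, and (b) a shared two-state co-activation process on a 1.5 s
grid during the padded (bout ± 5 s) grooming epochs: in each grid cell the
whole ensemble is either co-active (rate gain ``coactivation_gain``) or
quiescent (a compensating sub-unity gain keeping the mean at one).  These
discrete synchronous events are what make members of the *same* ensemble
co-fluctuate beyond the bout-locked modulation all planted units share, and
because they are confined to grooming epochs the resulting correlations are
grooming-specific.  On top of this, *every* unit — ensemble member or not —
carries a private mean-one log-normal rate gain drawn independently per grid
cell: real units are never homogeneous Poisson, and the private variability
is what distinguishes "fluctuating unit" from "member of an ensemble"
(shared fluctuation).  Private gains are independent across cells, so the
per-unit bin-shuffle null of the ensemble-count test remains exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GroomingBouts, SpikeData
from .grooming import KEYPOINT_NAMES, Pose3DTrack

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_PROFILES",
    "SessionConfig",
    "GroundTruth",
    "SyntheticSession",
    "sample_bout_schedule",
    "generate_spikes",
    "generate_pose",
    "simulate_session",
    "synthesize_waveform",
]

#: Recognised per-ensemble response profiles.
RESPONSE_PROFILES = (
    "step_up",
    "step_down",
    "transient_start",
    "transient_end",
    "sustained_suppressed",
    "none",
)

#: Grid (s) on which the shared within-ensemble rate jitter is piecewise constant.
JITTER_GRID_S = 1.5

#: Padding (s) around each bout inside which the shared jitter operates,
#: matching the ±5 s grooming windows the ensemble analysis uses.
BOUT_PAD_S = 5.0


@dataclass
class SessionConfig:
    """Ground-truth parameters of one synthetic session.

    Rates are in Hz, durations in seconds.  ``ensemble_sizes`` and
    ``response_profiles`` have one entry per planted ensemble; units not in
    any ensemble are independent Poisson processes.
    """

    session_duration_s: float = 7200.0
    n_spn: int = 55
    n_fsi: int = 5
    n_ensembles: int = 5
    ensemble_sizes: list = field(default_factory=lambda: [6, 6, 6, 6, 6])
    response_profiles: list = field(
        default_factory=lambda: [
            "step_up",
            "transient_start",
            "step_down",
            "transient_end",
            "step_up",
        ]
    )
    # SPN upper bound leaves headroom for grooming-epoch modulation so the
    # realized session-mean rate stays below the 10 Hz classification cap
    spn_rate_range_hz: tuple = (0.2, 7.0)
    fsi_rate_range_hz: tuple = (5.0, 25.0)
    modulation_gain: float = 5.0
    coactivation_prob: float = 0.4
    coactivation_gain: float = 2.2
    private_jitter_sigma: float = 0.85
    transient_halfwidth_s: float = 1.0
    groom_fraction: float = 0.041
    mean_bout_s: float = 12.4
    bout_sigma_log: float = 0.5
    mean_ibi_s: float = 258.0
    spatial_structure: bool = True
    full_waveforms: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be positive")
        if not (0 < self.groom_fraction < 0.5):
            raise ValueError("groom_fraction must lie in (0, 0.5)")
        if self.mean_bout_s <= 0 or self.mean_ibi_s <= 0:
            raise ValueError("bout and inter-bout means must be positive")
        for r in (*self.spn_rate_range_hz, *self.fsi_rate_range_hz):
            if r <= 0:
                raise ValueError("all rates must be positive")
        if len(self.ensemble_sizes) != self.n_ensembles:
            raise ValueError("one ensemble size per ensemble required")
        if len(self.response_profiles) != self.n_ensembles:
            raise ValueError("one response profile per ensemble required")
        for p in self.response_profiles:
            if p not in RESPONSE_PROFILES:
                raise ValueError(f"unknown response profile {p!r}")
        if any(s < 2 for s in self.ensemble_sizes):
            raise ValueError("ensembles need at least 2 units")
        if sum(self.ensemble_sizes) > self.n_spn + self.n_fsi:
            raise ValueError("sum(ensemble_sizes) exceeds the number of units")
        if self.modulation_gain <= 0:
            raise ValueError("modulation_gain must be positive")
        if not (0.0 <= self.coactivation_prob < 1.0):
            raise ValueError("coactivation_prob must lie in [0, 1)")
        if self.coactivation_gain < 1.0:
            raise ValueError("coactivation_gain must be >= 1")
        if self.coactivation_prob * self.coactivation_gain >= 1.0:
            raise ValueError(
                "coactivation_prob * coactivation_gain must stay below 1 so the "
                "quiescent-state gain remains positive (mean-one process)"
            )
        if self.private_jitter_sigma < 0:
            raise ValueError("private_jitter_sigma must be non-negative")

    @property
    def n_units(self) -> int:
        return self.n_spn + self.n_fsi


@dataclass
class GroundTruth:
    """What was planted: true cell types, memberships, profiles, and bouts."""

    unit_labels: np.ndarray  # 'SPN' / 'FSI' per unit
    ensemble_membership: np.ndarray  # ensemble index per unit, -1 = none
    profile_per_ensemble: list
    true_bouts: GroomingBouts
    baseline_rates_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.ensemble_membership)
        if len(m) and m.max(initial=-1) >= len(self.profile_per_ensemble):
            raise ValueError("membership index out of range")


@dataclass
class SyntheticSession:
    """One fully generated session plus its ground truth."""

    config: SessionConfig
    bouts: GroomingBouts
    spikes: SpikeData
    units: pd.DataFrame
    ground_truth: GroundTruth
    pose: Pose3DTrack | None = None
    waveforms: dict | None = None


# ---------------------------------------------------------------------------
# bout schedule
# ---------------------------------------------------------------------------

def sample_bout_schedule(cfg: SessionConfig, rng: np.random.Generator) -> GroomingBouts:
    """Draw a grooming bout schedule for one session.

    Bout durations are log-normal with mean ``cfg.mean_bout_s`` and log-space
    sigma ``cfg.bout_sigma_log``; gaps between bouts are exponential with mean
    ``cfg.mean_ibi_s``.  All bouts are contained in
    ``[5, session_duration_s - 5]`` so that ±5 s analysis flanks always exist.
    """
    lo, hi = 5.0, cfg.session_duration_s - 5.0
    if not np.isfinite(cfg.mean_ibi_s):
        return GroomingBouts.empty()
    mu = np.log(cfg.mean_bout_s) - 0.5 * cfg.bout_sigma_log**2
    t = lo + rng.exponential(cfg.mean_ibi_s)
    out = []
    while True:
        dur = rng.lognormal(mu, cfg.bout_sigma_log)
        if t + dur > hi:
            break
        out.append((t, t + dur))
        t = t + dur + rng.exponential(cfg.mean_ibi_s)
    if not out:
        warnings.warn(
            "session too short to fit a single grooming bout; empty schedule",
            stacklevel=2,
        )
        return GroomingBouts.empty()
    return GroomingBouts.from_pairs(out)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping intervals, sorted."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _active_epochs(profile: str, bouts: GroomingBouts, cfg: SessionConfig) -> tuple:
    """(intervals, gain) for one ensemble's response profile."""
    g = cfg.modulation_gain
    h = cfg.transient_halfwidth_s
    D = cfg.session_duration_s
    iv = bouts.intervals
    if profile == "none" or len(iv) == 0:
        return np.empty((0, 2)), 1.0
    if profile == "step_up":
        return iv.copy(), g
    if profile in ("step_down", "sustained_suppressed"):
        return iv.copy(), 1.0 / g
    if profile == "transient_start":
        win = np.column_stack([iv[:, 0] - h, iv[:, 0] + h])
    elif profile == "transient_end":
        win = np.column_stack([iv[:, 1] - h, iv[:, 1] + h])
    else:  # pragma: no cover - guarded by SessionConfig validation
        raise ValueError(f"unknown response profile {profile!r}")
    return _merge_intervals(np.clip(win, 0.0, D)), g


def _padded_segments(bouts: GroomingBouts, duration_s: float, pad: float = BOUT_PAD_S) -> np.ndarray:
    """Bout ± pad windows, clipped to the session and merged where they overlap."""
    if len(bouts) == 0:
        return np.empty((0, 2))
    padded = np.column_stack([bouts.starts - pad, bouts.ends + pad])
    return _merge_intervals(np.clip(padded, 0.0, duration_s))


def _grid_cell_edges(segments: np.ndarray) -> np.ndarray:
    """Left edges of the 1.5 s grid cells tiling each segment (trailing
    partial cells kept)."""
    edges = [np.arange(s, e, JITTER_GRID_S) for s, e in segments]
    return np.concatenate(edges) if edges else np.empty(0)


def _coactivation_factors(
    n_cells: int, prob: float, gain: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-one two-state co-activation gains, one per grid cell: ``gain``
    with probability ``prob``, else the compensating quiescent gain."""
    if n_cells == 0 or prob == 0.0:
        return np.ones(n_cells)
    lo = (1.0 - prob * gain) / (1.0 - prob)
    return np.where(rng.random(n_cells) < prob, gain, lo)


def _private_factors(
    n_cells: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-one log-normal private rate gains, independent per grid cell."""
    if n_cells == 0 or sigma == 0.0:
        return np.ones(n_cells)
    return rng.lognormal(-0.5 * sigma**2, sigma, size=n_cells)


def _segment_rate(
    mids: np.ndarray,
    base: float,
    active: np.ndarray,
    gain: float,
    jit_edges: np.ndarray,
    jit_factors: np.ndarray,
    jit_segments: np.ndarray,
) -> np.ndarray:
    rate = np.full(len(mids), base)
    if len(active):
        idx = np.searchsorted(active[:, 0], mids, side="right") - 1
        inside = (idx >= 0) & (mids < active[np.clip(idx, 0, None), 1])
        rate[inside] *= gain
    if len(jit_edges):
        seg_idx = np.searchsorted(jit_segments[:, 0], mids, side="right") - 1
        in_seg = (seg_idx >= 0) & (mids < jit_segments[np.clip(seg_idx, 0, None), 1])
        cell = np.searchsorted(jit_edges, mids, side="right") - 1
        rate[in_seg] *= jit_factors[np.clip(cell, 0, None)][in_seg]
    return rate


def _simulate_inhomogeneous_poisson(
    breakpoints: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    widths = np.diff(breakpoints)
    counts = rng.poisson(rates * widths)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    lefts = np.repeat(breakpoints[:-1], counts)
    spans = np.repeat(widths, counts)
    return np.sort(lefts + rng.random(total) * spans)


def generate_spikes(
    cfg: SessionConfig, bouts: GroomingBouts, rng: np.random.Generator
) -> tuple[SpikeData, pd.DataFrame, GroundTruth]:
    """Generate the session's spike trains, unit feature table, and ground truth.

    Each unit is an inhomogeneous Poisson process: a baseline rate drawn from
    the cell type's range, multiplied by its ensemble's gain during the
    profile's active epoch and by the ensemble's shared jitter during padded
    bouts.  Waveform features are drawn well inside the classification
    regions, so downstream classification reproduces the true labels exactly;
    when ``cfg.spatial_structure`` is set, members of an ensemble share a
    probe shank and sit near a common depth.
    """
    if len(bouts) and (bouts.starts[0] < 0 or bouts.ends[-1] > cfg.session_duration_s):
        raise ValueError("bouts must lie within the session")
    n = cfg.n_units
    D = cfg.session_duration_s
    labels = np.array(["SPN"] * cfg.n_spn + ["FSI"] * cfg.n_fsi)

    # ensemble membership: drawn from SPNs first (striatal ensembles are
    # overwhelmingly SPN), spilling into FSIs only if the SPN pool runs out
    membership = np.full(n, -1)
    pool = np.concatenate([rng.permutation(cfg.n_spn), cfg.n_spn + rng.permutation(cfg.n_fsi)])
    cursor = 0
    for k, size in enumerate(cfg.ensemble_sizes):
        membership[pool[cursor : cursor + size]] = k
        cursor += size

    base = np.where(
        labels == "SPN",
        rng.uniform(*cfg.spn_rate_range_hz, size=n),
        rng.uniform(*cfg.fsi_rate_range_hz, size=n),
    )

    jit_segments = _padded_segments(bouts, D)
    cell_edges = _grid_cell_edges(jit_segments)
    epochs = [_active_epochs(p, bouts, cfg) for p in cfg.response_profiles]
    shared = [
        _coactivation_factors(
            len(cell_edges), cfg.coactivation_prob, cfg.coactivation_gain, rng
        )
        for _ in range(cfg.n_ensembles)
    ]

    times = []
    for i in range(n):
        k = membership[i]
        if k >= 0:
            active, gain = epochs[k]
        else:
            active, gain = np.empty((0, 2)), 1.0
        factors = _private_factors(len(cell_edges), cfg.private_jitter_sigma, rng)
        if k >= 0:
            factors = factors * shared[k]
        pts = [np.array([0.0, D]), active.ravel()]
        if len(cell_edges):
            pts += [cell_edges, jit_segments.ravel()]
        bp = np.unique(np.clip(np.concatenate(pts), 0.0, D))
        mids = 0.5 * (bp[:-1] + bp[1:])
        rates = _segment_rate(
            mids, base[i], active, gain, cell_edges, factors, jit_segments
        )
        times.append(_simulate_inhomogeneous_poisson(bp, rates, rng))

    positions = _draw_positions(labels, membership, cfg, rng)
    spikes = SpikeData(np.arange(n), times, D, positions)

    width = np.where(labels == "SPN", rng.uniform(180, 300, n), rng.uniform(80, 140, n))
    pvi = np.where(labels == "SPN", rng.uniform(550, 900, n), rng.uniform(250, 450, n))
    units = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "x_um": positions[:, 0],
            "depth_um": positions[:, 1],
            "peak_width_us": width,
            "peak_valley_us": pvi,
            "mean_rate_hz": spikes.mean_rates(),
        }
    )

    waveforms = None
    if cfg.full_waveforms:
        waveforms = {
            int(u): synthesize_waveform(width[i], pvi[i])
            for i, u in enumerate(units["unit_id"])
        }

    gt = GroundTruth(
        unit_labels=labels,
        ensemble_membership=membership,
        profile_per_ensemble=list(cfg.response_profiles),
        true_bouts=bouts,
        baseline_rates_hz=base,
    )
    if waveforms is not None:
        units.attrs["waveforms"] = waveforms
    return spikes, units, gt


def _draw_positions(
    labels: np.ndarray, membership: np.ndarray, cfg: SessionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Probe-plane positions: 4 shanks at 200 um pitch, depth along each shank."""
    n = len(labels)
    shanks = np.array([0.0, 200.0, 400.0, 600.0])
    x = rng.choice(shanks, size=n)
    depth = rng.uniform(0.0, 600.0, size=n)
    if cfg.spatial_structure:
        for k in range(cfg.n_ensembles):
            members = np.flatnonzero(membership == k)
            cx = rng.choice(shanks)
            cd = rng.uniform(100.0, 500.0)
            x[members] = cx
            depth[members] = np.clip(cd + rng.normal(0.0, 40.0, len(members)), 0.0, 600.0)
    return np.column_stack([x, depth])


def synthesize_waveform(
    peak_width_us: float, peak_valley_us: float, sampling_rate_hz: float = 30000.0,
    length_ms: float = 4.0,
) -> tuple[np.ndarray, float]:
    """Biphasic mean-waveform template with a prescribed trough FWHM and
    trough-to-peak interval.

    Returns ``(waveform, sampling_rate_hz)``.  The dominant deflection is a
    negative Gaussian trough whose full width at half maximum is
    ``peak_width_us``; a smaller positive afterpeak follows at
    ``peak_valley_us``.
    """
    t = np.arange(0.0, length_ms * 1e-3, 1.0 / sampling_rate_hz)
    t0 = 1.0e-3
    s1 = peak_width_us * 1e-6 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    s2 = 1.6 * s1
    w = -np.exp(-((t - t0) ** 2) / (2 * s1**2)) + 0.4 * np.exp(
        -((t - t0 - peak_valley_us * 1e-6) ** 2) / (2 * s2**2)
    )
    return w, sampling_rate_hz


# ---------------------------------------------------------------------------
# 3D pose
# ---------------------------------------------------------------------------

# keypoint placement relative to the body centre: (forward, lateral, height).
# Walking: body stretched horizontally, snout low, paws on the floor.
_WALK_OFFSETS = {
    "snout": (2.2, 0.0, 1.2),
    "eye_L": (1.8, 0.35, 1.8),
    "eye_R": (1.8, -0.35, 1.8),
    "ear_L": (1.5, 0.5, 2.0),
    "ear_R": (1.5, -0.5, 2.0),
    "shoulder_L": (1.0, 0.5, 1.5),
    "shoulder_R": (1.0, -0.5, 1.5),
    "elbow_L": (0.8, 0.45, 0.9),
    "elbow_R": (0.8, -0.45, 0.9),
    "wrist_L": (0.9, 0.4, 0.4),
    "wrist_R": (0.9, -0.4, 0.4),
    "paw_L": (1.1, 0.35, 0.1),
    "paw_R": (1.1, -0.35, 0.1),
    "hind_L": (-1.2, 0.5, 0.1),
    "hind_R": (-1.2, -0.5, 0.1),
}

# Grooming: rearing hunched over the haunches, snout high, paws at the snout.
_GROOM_OFFSETS = {
    "snout": (0.5, 0.0, 5.0),
    "eye_L": (0.45, 0.3, 4.6),
    "eye_R": (0.45, -0.3, 4.6),
    "ear_L": (0.35, 0.45, 4.5),
    "ear_R": (0.35, -0.45, 4.5),
    "shoulder_L": (0.3, 0.4, 3.6),
    "shoulder_R": (0.3, -0.4, 3.6),
    "elbow_L": (0.5, 0.4, 3.2),
    "elbow_R": (0.5, -0.4, 3.2),
    "wrist_L": (0.55, 0.3, 3.8),
    "wrist_R": (0.55, -0.3, 3.8),
    "paw_L": (0.5, 0.25, 4.3),
    "paw_R": (0.5, -0.25, 4.3),
    "hind_L": (-0.5, 0.4, 0.1),
    "hind_R": (-0.5, -0.4, 0.1),
}

_ARENA_RADIUS = 8.0


def generate_pose(
    bouts: GroomingBouts,
    frame_rate_hz: float = 125.0,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
    keypoint_jitter_sd: float = 0.0,
    groom_osc_hz: float = 4.0,
) -> Pose3DTrack:
    """Synthesize a 15-keypoint 3D pose track for one session.

    Outside bouts the animal performs smooth locomotion with a stretched,
    low-snout posture (which violates the rearing predicates of the grooming
    heuristic on every frame); inside bouts it freezes in place in a rearing
    posture with the paws oscillating near the snout, satisfying every
    predicate.  ``keypoint_jitter_sd`` adds isotropic Gaussian noise to all
    coordinates.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    rng = np.random.default_rng() if rng is None else rng
    if duration_s is None:
        if len(bouts) == 0:
            raise ValueError("duration_s required when the bout list is empty")
        duration_s = float(bouts.ends[-1] + 5.0)
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz

    # smooth bounded 2D path: low-passed random walk squashed into the arena
    from scipy.ndimage import gaussian_filter1d

    raw = np.cumsum(rng.normal(0.0, 1.0, size=(n, 2)), axis=0)
    path = gaussian_filter1d(raw, sigma=max(1.0, 0.5 * frame_rate_hz), axis=0)
    scale = np.std(path, axis=0)
    scale[scale == 0] = 1.0
    pos = _ARENA_RADIUS * 0.6 * np.tanh(path / (2.0 * scale))
    # smooth heading random walk, decoupled from the path for simplicity
    theta = gaussian_filter1d(
        np.cumsum(rng.normal(0.0, 0.08, size=n)), sigma=max(1.0, 0.2 * frame_rate_hz)
    )

    # freeze position and heading at the bout-entry frame during each bout
    groom = np.zeros(n, dtype=bool)
    src = np.arange(n)
    for s, e in bouts:
        f0 = int(np.ceil(s * frame_rate_hz))
        f1 = min(int(np.ceil(e * frame_rate_hz)), n)
        if f1 > f0:
            groom[f0:f1] = True
            src[f0:f1] = f0
    pos, theta = pos[src], theta[src]

    h = np.column_stack([np.cos(theta), np.sin(theta)])
    nv = np.column_stack([-np.sin(theta), np.cos(theta)])

    coords = np.empty((n, len(KEYPOINT_NAMES), 3), dtype=np.float32)
    osc = 0.15 * np.sin(2.0 * np.pi * groom_osc_hz * t)
    for k, name in enumerate(KEYPOINT_NAMES):
        fw_w, lat_w, z_w = _WALK_OFFSETS[name]
        fw_g, lat_g, z_g = _GROOM_OFFSETS[name]
        fw = np.where(groom, fw_g, fw_w)
        lat = np.where(groom, lat_g, lat_w)
        z = np.where(groom, z_g, z_w)
        if name in ("paw_L", "paw_R"):
            z = z + np.where(groom, osc, 0.0)
        xy = pos + fw[:, None] * h + lat[:, None] * nv
        coords[:, k, :2] = xy
        coords[:, k, 2] = z
    if keypoint_jitter_sd > 0:
        coords += rng.normal(0.0, keypoint_jitter_sd, size=coords.shape).astype(np.float32)

    return Pose3DTrack(
        frame_rate_hz=frame_rate_hz,
        frames=np.arange(n),
        keypoints=tuple(KEYPOINT_NAMES),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# one-call session
# ---------------------------------------------------------------------------

def simulate_session(
    cfg: SessionConfig,
    make_pose: bool = False,
    pose_frame_rate_hz: float = 125.0,
    pose_jitter_sd: float = 0.0,
) -> SyntheticSession:
    """Generate a complete session from one config.

    The config seed fans out to independent child streams for the bout
    schedule, the spike trains, and the pose track, so each stage is
    reproducible on its own.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_sched, r_spk, r_pose = (np.random.default_rng(s) for s in ss.spawn(3))
    bouts = sample_bout_schedule(cfg, r_sched)
    spikes, units, gt = generate_spikes(cfg, bouts, r_spk)
    pose = None
    if make_pose:
        pose = generate_pose(
            bouts,
            frame_rate_hz=pose_frame_rate_hz,
            rng=r_pose,
            duration_s=cfg.session_duration_s,
            keypoint_jitter_sd=pose_jitter_sd,
        )
    return SyntheticSession(
        config=cfg,
        bouts=bouts,
        spikes=spikes,
        units=units,
        ground_truth=gt,
        pose=pose,
        waveforms=units.attrs.get("waveforms"),
    )
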