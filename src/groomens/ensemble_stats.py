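"""Characterization of detected ensembles.

Correlation contrasts and their AUC, probe-plane distance splits, linear
time-warping of bout activity onto a common base, duration-matched bootstrap
null bands, peak-time summaries, percent-active-unit variants, and
across-session cluster summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata, sem

from .core import SpikeData
from .ensembles import (
    BIN_SIZE_S,
    PAD_S,
    SMOOTH_SIGMA_S,
    EnsembleAssignment,
    GroomingMatrix,
    _bin_segments,
    _smooth_by_segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WarpedActivity",
    "BootstrapNull",
    "pairwise_correlation_split",
    "distribution_auc",
    "pairwise_distance_split",
    "cumulative_curves",
    "timewarp_bout_activity",
    "ensemble_traces",
    "bootstrap_null",
    "band_escape_runs",
    "is_significant_ensemble",
    "ensemble_peak_times",
    "fraction_active_units",
    "cluster_summary",
]


def _rows_and_labels(matrix, assignment) -> tuple[np.ndarray, np.ndarray]:
    # correlations are computed on the unsmoothed normalized rows: the
    # Gaussian filter correlates neighbouring bins, which widens the null
    # spread of between-pair correlations without adding information
    rows = (
        matrix.normalized if isinstance(matrix, GroomingMatrix) else np.asarray(matrix)
    )
    labels = (
        assignment.labels
        if isinstance(assignment, EnsembleAssignment)
        else np.asarray(assignment)
    )
    if rows.shape[0] != len(labels):
        raise ValueError("matrix rows and assignment labels must align")
    return rows, labels


def pairwise_correlation_split(matrix, assignment) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations per unit pair, split within- vs between-cluster.

    ``within`` collects pairs whose two units share a cluster; ``between``
    all other pairs, including pairs with unassigned units.  Zero-variance
    units are skipped (their pair count is logged).
    """
    rows, labels = _rows_and_labels(matrix, assignment)
    ok = rows.std(axis=1) > 0
    n_skipped = len(labels) - int(ok.sum())
    if n_skipped:
        logger.info("correlation split: skipped %d zero-variance units", n_skipped)
    idx = np.flatnonzero(ok)
    r = np.corrcoef(rows[idx])
    within, between = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            la, lb = labels[idx[a]], labels[idx[b]]
            (within if (la >= 0 and la == lb) else between).append(r[a, b])
    return np.asarray(within), np.asarray(between)


def distribution_auc(x, y) -> float:
    """P(random draw from x > random draw from y), ties counted 1/2.

    The rank (Mann-Whitney) construction; satisfies
    ``auc(x, y) == 1 - auc(y, x)``.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    return float(u / (len(x) * len(y)))


def pairwise_distance_split(
    positions: np.ndarray, assignment
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean probe-plane distances per unit pair, split within/between.

    ``positions`` is (n_units, 2): shank axis (um) x depth (um).  Pairs with
    a missing (NaN) position are skipped.
    """
    positions = np.asarray(positions, dtype=float)
    labels = (
        assignment.labels
        if isinstance(assignment, EnsembleAssignment)
        else np.asarray(assignment)
    )
    within, between = [], []
    n = len(labels)
    for a in range(n):
        for b in range(a + 1, n):
            if np.any(np.isnan(positions[[a, b]])):
                continue
            d = float(np.linalg.norm(positions[a] - positions[b]))
            la, lb = labels[a], labels[b]
            (within if (la >= 0 and la == lb) else between).append(d)
    return np.asarray(within), np.asarray(between)


def cumulative_curves(samples: list, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean ± SEM of empirical CDFs across sessions/animals on a common grid."""
    curves = []
    for s in samples:
        s = np.sort(np.asarray(s, dtype=float))
        if len(s) == 0:
            continue
        curves.append(np.searchsorted(s, grid, side="right") / len(s))
    curves = np.asarray(curves)
    if len(curves) == 0:
        raise ValueError("no non-empty samples")
    se = sem(curves, axis=0) if len(curves) > 1 else np.zeros(len(grid))
    return curves.mean(axis=0), se


# ---------------------------------------------------------------------------
# linear time warping
# ---------------------------------------------------------------------------


@dataclass
class WarpedActivity:
    """Per-bout activity on a common time base.

    ``data`` has shape (n_bouts, n_rows, flank_bins + target_len_bins +
    flank_bins).  The ±5 s flanks are copied unwarped; only the bout core is
    linearly rescaled.
    """

    data: np.ndarray
    target_len_bins: int
    flank_bins: int
    bin_size_s: float
    normalization: str = "unit_minmax"

    @property
    def n_bouts(self) -> int:
        return self.data.shape[0]

    @property
    def total_bins(self) -> int:
        return self.data.shape[2]

    def bout_average(self) -> np.ndarray:
        """(n_rows, total_bins) mean over bouts."""
        return self.data.mean(axis=0)


def _warp_core(core: np.ndarray, target: int) -> np.ndarray:
    """Linearly interpolate rows x core_bins onto rows x target bins."""
    L = core.shape[1]
    if L == 1:
        logger.info("bout core shorter than 2 bins; nearest-sample duplication")
        return np.repeat(core, target, axis=1)
    x = np.linspace(0.0, 1.0, target)
    xp = np.linspace(0.0, 1.0, L)
    return np.vstack([np.interp(x, xp, row) for row in core])


def timewarp_bout_activity(
    m: GroomingMatrix,
    rows: np.ndarray | None = None,
    target_len_bins: int | None = None,
    pad_s: float = PAD_S,
) -> WarpedActivity:
    """Rescale each padded-bout segment onto a common normalized time base.

    ``rows`` defaults to the smoothed normalized matrix; any aligned row
    matrix (e.g. ensemble-mean traces or raw counts) can be warped instead.
    The flanks (``floor(pad_s / bin)`` bins on each side) are copied
    unchanged; the core is linearly interpolated to ``target_len_bins``
    points (default: the median core length over the session's segments).
    """
    rows = m.smoothed if rows is None else np.asarray(rows, dtype=float)
    if rows.shape[1] != m.n_bins:
        raise ValueError("rows must align with the matrix bins")
    flank = int(np.floor(pad_s / m.bin_size_s))
    cores = []
    seg_slices = []
    for k in range(len(m.segments)):
        sel = np.flatnonzero(m.segment_ids == k)
        if len(sel) < 2 * flank + 1:
            logger.info("segment %d too short for flanks; skipped", k)
            continue
        seg_slices.append(sel)
        cores.append(len(sel) - 2 * flank)
    if not seg_slices:
        raise ValueError("no segment long enough to warp")
    if target_len_bins is None:
        target_len_bins = int(np.median(cores))
    if target_len_bins < 2:
        target_len_bins = 2
    out = np.empty((len(seg_slices), rows.shape[0], 2 * flank + target_len_bins))
    for j, sel in enumerate(seg_slices):
        seg = rows[:, sel]
        out[j, :, :flank] = seg[:, :flank]
        out[j, :, flank : flank + target_len_bins] = _warp_core(
            seg[:, flank : seg.shape[1] - flank], target_len_bins
        )
        out[j, :, flank + target_len_bins :] = seg[:, seg.shape[1] - flank :]
    return WarpedActivity(
        data=out,
        target_len_bins=target_len_bins,
        flank_bins=flank,
        bin_size_s=m.bin_size_s,
    )


def ensemble_traces(m: GroomingMatrix, assignment: EnsembleAssignment) -> np.ndarray:
    """(n_ensembles, n_bins) ensemble-average activity: the mean of the
    member units' smoothed normalized rows."""
    n_clusters = assignment.n_clusters
    if n_clusters == 0:
        raise ValueError("assignment contains no clusters")
    return np.vstack(
        [m.smoothed[assignment.members(c)].mean(axis=0) for c in range(n_clusters)]
    )


# ---------------------------------------------------------------------------
# bootstrap null band
# ---------------------------------------------------------------------------


@dataclass
class BootstrapNull:
    """Mean and 2.5/97.5 percentile band of duration-matched null activity."""

    n_windows: int
    mean: np.ndarray
    p_low: np.ndarray
    p_high: np.ndarray
    target_len_bins: int
    flank_bins: int

    def __post_init__(self) -> None:
        if np.any(self.p_low > self.p_high + 1e-12):
            raise ValueError("band ordering violated")


def _window_trace(
    times: list,
    start: float,
    dur: float,
    norm_min: np.ndarray,
    norm_max: np.ndarray,
    target_len_bins: int,
    flank: int,
    bin_size_s: float,
    pad_s: float,
    smooth_sigma_s: float,
) -> np.ndarray | None:
    """Process one window exactly like a padded bout and return the
    population-average warped trace, or None if the window is too short."""
    seg = np.array([[start - pad_s, start + dur + pad_s]])
    counts, _, widths, seg_ids = _bin_segments(times, seg, bin_size_s)
    if counts.shape[1] < 2 * flank + 1:
        return None
    rates = counts / widths
    span = norm_max - norm_min
    span = np.where(span == 0, 1.0, span)
    normalized = (rates - norm_min[:, None]) / span[:, None]
    smoothed = _smooth_by_segment(normalized, seg_ids, smooth_sigma_s / bin_size_s)
    trace = smoothed.mean(axis=0, keepdims=True)
    nb = trace.shape[1]
    out = np.empty(2 * flank + target_len_bins)
    out[:flank] = trace[0, :flank]
    out[flank : flank + target_len_bins] = _warp_core(
        trace[:, flank : nb - flank], target_len_bins
    )[0]
    out[flank + target_len_bins :] = trace[0, nb - flank :]
    return out


def bootstrap_null(
    spikes: SpikeData,
    bout_duration_pool,
    norm_min: np.ndarray,
    norm_max: np.ndarray,
    target_len_bins: int,
    n_windows: int = 1000,
    rng: np.random.Generator | None = None,
    bin_size_s: float = BIN_SIZE_S,
    pad_s: float = PAD_S,
    smooth_sigma_s: float = SMOOTH_SIGMA_S,
    edge_margin_s: float = 5.0,
    max_retries: int = 1000,
) -> BootstrapNull:
    """Duration-matched bootstrap null for one ensemble's grooming response.

    ``spikes`` holds the member units only.  Each of the ``n_windows`` null
    windows draws its duration (with replacement) from the observed bout
    duration pool and its start uniformly from ``edge_margin_s`` into the
    session to ``edge_margin_s`` before the end; the window is then padded,
    binned, normalized with the *session's* per-unit factors, smoothed,
    population-averaged, and warped — identically to a real bout.  Windows
    are allowed to overlap actual grooming bouts.
    """
    rng = np.random.default_rng() if rng is None else rng
    pool = np.asarray(bout_duration_pool, dtype=float)
    if len(pool) == 0:
        raise ValueError("bout duration pool must be non-empty")
    D = spikes.duration_s
    flank = int(np.floor(pad_s / bin_size_s))
    traces = np.empty((n_windows, 2 * flank + target_len_bins))
    for w in range(n_windows):
        for _ in range(max_retries):
            dur = float(rng.choice(pool))
            hi = D - edge_margin_s - dur
            if hi <= edge_margin_s:
                continue
            start = rng.uniform(edge_margin_s, hi)
            trace = _window_trace(
                spikes.times, start, dur, norm_min, norm_max,
                target_len_bins, flank, bin_size_s, pad_s, smooth_sigma_s,
            )
            if trace is not None:
                break
        else:
            raise RuntimeError("could not place a null window within the session")
        traces[w] = trace
    return BootstrapNull(
        n_windows=n_windows,
        mean=traces.mean(axis=0),
        p_low=np.percentile(traces, 2.5, axis=0),
        p_high=np.percentile(traces, 97.5, axis=0),
        target_len_bins=target_len_bins,
        flank_bins=flank,
    )


def band_escape_runs(observed: np.ndarray, null: BootstrapNull) -> np.ndarray:
    """Lengths of contiguous runs of bins where the observed trace leaves the
    null band."""
    outside = (observed < null.p_low) | (observed > null.p_high)
    runs, count = [], 0
    for o in outside:
        if o:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return np.asarray(runs, dtype=int)


def is_significant_ensemble(
    observed: np.ndarray, null: BootstrapNull, min_run_bins: int = 2
) -> bool:
    """An ensemble's grooming response is called significant when the
    observed warped trace leaves the bootstrap band for at least
    ``min_run_bins`` contiguous bins."""
    runs = band_escape_runs(observed, null)
    return bool(len(runs) and runs.max() >= min_run_bins)


# ---------------------------------------------------------------------------
# peak times, active fractions, cluster summaries
# ---------------------------------------------------------------------------


def ensemble_peak_times(bout_averaged: np.ndarray) -> np.ndarray:
    """Peak bin per ensemble of the bout-averaged, [0,1]-normalized trace.

    Ties resolve to the earliest bin (logged when they occur).
    """
    traces = np.atleast_2d(np.asarray(bout_averaged, dtype=float))
    peaks = np.empty(len(traces), dtype=int)
    for i, tr in enumerate(traces):
        span = tr.max() - tr.min()
        norm = (tr - tr.min()) / span if span > 0 else np.zeros_like(tr)
        if span == 0:
            logger.info("constant ensemble trace; peak tie resolves to bin 0")
        peaks[i] = int(np.argmax(norm))
    return peaks


def fraction_active_units(
    m: GroomingMatrix, assignment: EnsembleAssignment, min_spikes: int = 1
) -> np.ndarray:
    """(n_ensembles, n_bins) fraction of member units with at least
    ``min_spikes`` raw spikes in each bin."""
    n_clusters = assignment.n_clusters
    if n_clusters == 0:
        raise ValueError("assignment contains no clusters")
    active = m.counts >= min_spikes
    return np.vstack(
        [active[assignment.members(c)].mean(axis=0) for c in range(n_clusters)]
    )


def cluster_summary(sessions: list) -> tuple[pd.DataFrame, dict]:
    """Across-session cluster statistics and unit-count regressions.

    ``sessions`` is a list of ``(assignment, unit_labels)`` pairs, where
    ``unit_labels`` gives each unit's cell type ('SPN'/'FSI').  Returns a
    per-session summary table and ordinary least-squares fits of the cluster
    count and the mean cluster size against the session's unit count
    (R² and two-sided slope p-value each).
    """
    if len(sessions) < 2:
        raise ValueError("at least 2 sessions required")
    records = []
    for k, (assignment, unit_labels) in enumerate(sessions):
        labels = assignment.labels
        unit_labels = np.asarray(unit_labels)
        sizes = assignment.cluster_sizes()
        comp = {"spn_only": 0, "fsi_only": 0, "mixed": 0}
        for c in range(assignment.n_clusters):
            kinds = set(unit_labels[assignment.members(c)])
            if kinds == {"SPN"}:
                comp["spn_only"] += 1
            elif kinds == {"FSI"}:
                comp["fsi_only"] += 1
            else:
                comp["mixed"] += 1
        records.append(
            {
                "session": k,
                "n_units": len(labels),
                "n_clusters": assignment.n_clusters,
                "mean_cluster_size": float(sizes.mean()) if len(sizes) else np.nan,
                "median_cluster_size": float(np.median(sizes)) if len(sizes) else np.nan,
                "pct_clustered": 100.0 * float(np.mean(labels >= 0)),
                **comp,
            }
        )
    table = pd.DataFrame.from_records(records)

    def _fit(y: pd.Series) -> dict:
        x = table["n_units"].to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
        ok = np.isfinite(yv)
        if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(yv[ok]) == 0:
            return {"slope": 0.0, "intercept": float(np.nanmean(yv)), "r2": 0.0, "p": 1.0}
        res = linregress(x[ok], yv[ok])
        return {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r2": float(res.rvalue**2),
            "p": float(res.pvalue),
        }

    fits = {
        "clusters_vs_units": _fit(table["n_clusters"]),
        "mean_size_vs_units": _fit(table["mean_cluster_size"]),
    }
    return table, fits
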