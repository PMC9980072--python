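"""Ensemble detection from grooming-restricted population activity.

The session's spiking is restricted to grooming bouts padded by ±5 s,
binned at 1.5 s (0.667 Hz), min-max normalized per unit, and smoothed with a
3 s Gaussian.  On this matrix two questions are answered:

* *how many* ensembles — a shuffle-eigenvalue test counts eigenvalues of the
  unit-unit correlation matrix exceeding the 99th percentile of the maximum
  eigenvalue obtained when every unit's time bins are permuted independently;
* *which units* — meta-k-means: many k-means runs over units (distances on
  z-scored rates, so proximity means co-fluctuation), a co-assignment
  frequency matrix, intermediate clusters from pairs co-assigned in >80% of
  runs, and a final greedy merging step scored by silhouette.

Binned activity is expressed as rates (count / bin width) so that the kept
partial trailing bins of short segments do not imprint a shared count deficit
on every unit; with full-width bins rates and counts are identical after
normalization or z-scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import GroomingBouts, SpikeData
from .synthetic import _merge_intervals  # interval union helper

logger = logging.getLogger(__name__)

__all__ = [
    "GroomingMatrix",
    "EnsembleCountEstimate",
    "EnsembleAssignment",
    "build_grooming_matrix",
    "build_session_matrix",
    "estimate_ensemble_count",
    "meta_kmeans",
]

BIN_SIZE_S = 1.5
PAD_S = 5.0
SMOOTH_SIGMA_S = 3.0
MIN_UNITS = 30


@dataclass
class GroomingMatrix:
    """Units x bins activity restricted to padded grooming segments.

    ``counts`` are raw spike counts, ``rates`` width-normalized counts,
    ``normalized`` per-unit min-max of the rates (in [0, 1] for non-constant
    rows), and ``smoothed`` the Gaussian-filtered normalized matrix (filtered
    within each segment independently, so activity never leaks across
    non-contiguous times).  ``segment_ids`` maps each bin to its source
    padded segment and ``segments`` gives each segment's (start_s, end_s).
    """

    unit_ids: np.ndarray
    bin_size_s: float
    bin_start_times_s: np.ndarray
    bin_widths_s: np.ndarray
    counts: np.ndarray
    rates: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    segment_ids: np.ndarray
    segments: np.ndarray  # (n_segments, 2)
    norm_min: np.ndarray
    norm_max: np.ndarray
    partial_bin: np.ndarray  # True where the bin is width-truncated

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def _bin_segments(
    times: list, segments: np.ndarray, bin_size_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bin each unit within each segment; bins tile from the segment start
    and the trailing partial bin is kept.  Returns (counts, starts, widths,
    segment_ids)."""
    starts, widths, seg_ids = [], [], []
    for k, (s, e) in enumerate(segments):
        nb = int(np.ceil((e - s) / bin_size_s - 1e-12))
        st = s + bin_size_s * np.arange(nb)
        starts.append(st)
        widths.append(np.minimum(st + bin_size_s, e) - st)
        seg_ids.append(np.full(nb, k))
    starts = np.concatenate(starts) if starts else np.empty(0)
    widths = np.concatenate(widths) if widths else np.empty(0)
    seg_ids = np.concatenate(seg_ids) if seg_ids else np.empty(0, dtype=int)

    counts = np.zeros((len(times), len(starts)), dtype=np.int64)
    for i, t in enumerate(times):
        lo = np.searchsorted(t, starts)
        hi = np.searchsorted(t, starts + widths)
        counts[i] = hi - lo
    return counts, starts, widths, seg_ids


def _smooth_by_segment(
    rows: np.ndarray, seg_ids: np.ndarray, sigma_bins: float
) -> np.ndarray:
    out = np.empty_like(rows)
    for k in np.unique(seg_ids):
        m = seg_ids == k
        out[:, m] = gaussian_filter1d(
            rows[:, m], sigma=sigma_bins, axis=1, mode="reflect", truncate=4.0
        )
    return out


def _assemble_matrix(
    spikes: SpikeData, segments: np.ndarray, bin_size_s: float, smooth_sigma_s: float
) -> GroomingMatrix:
    counts, starts, widths, seg_ids = _bin_segments(spikes.times, segments, bin_size_s)
    rates = counts / widths
    lo = rates.min(axis=1, keepdims=True)
    hi = rates.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0  # constant rows (incl. all-zero) stay flat: 0/0 guard
    normalized = (rates - lo) / span
    smoothed = _smooth_by_segment(normalized, seg_ids, smooth_sigma_s / bin_size_s)
    return GroomingMatrix(
        unit_ids=spikes.unit_ids,
        bin_size_s=bin_size_s,
        bin_start_times_s=starts,
        bin_widths_s=widths,
        counts=counts,
        rates=rates,
        normalized=normalized,
        smoothed=smoothed,
        segment_ids=seg_ids,
        segments=np.asarray(segments, dtype=float),
        norm_min=lo.ravel(),
        norm_max=hi.ravel(),
        partial_bin=widths < bin_size_s - 1e-12,
    )


def build_grooming_matrix(
    spikes: SpikeData,
    bouts: GroomingBouts,
    bin_size_s: float = BIN_SIZE_S,
    pad_s: float = PAD_S,
    smooth_sigma_s: float = SMOOTH_SIGMA_S,
    min_units: int = MIN_UNITS,
) -> GroomingMatrix:
    """Build the grooming activity matrix for one session.

    Each bout is padded by ``pad_s`` on both sides (overlapping padded
    windows are merged into one segment), binned at ``bin_size_s`` from the
    segment start keeping the trailing partial bin, and the segments are
    concatenated.  Min-max normalization is computed over the concatenated
    matrix; smoothing is applied within each segment independently.
    """
    if spikes.n_units < min_units:
        raise ValueError(
            f"ensemble identification requires at least {min_units} units "
            f"(got {spikes.n_units})"
        )
    if len(bouts) == 0:
        raise ValueError("at least one grooming bout required")
    padded = np.column_stack([bouts.starts - pad_s, bouts.ends + pad_s])
    segments = _merge_intervals(np.clip(padded, 0.0, spikes.duration_s))
    return _assemble_matrix(spikes, segments, bin_size_s, smooth_sigma_s)


def build_session_matrix(
    spikes: SpikeData,
    bin_size_s: float = BIN_SIZE_S,
    smooth_sigma_s: float = SMOOTH_SIGMA_S,
) -> GroomingMatrix:
    """Whole-session matrix with the same binning/normalization/smoothing as
    the grooming matrix, treating the full session as one segment — so a
    grooming-vs-session contrast isolates the time mask alone."""
    segments = np.array([[0.0, spikes.duration_s]])
    return _assemble_matrix(spikes, segments, bin_size_s, smooth_sigma_s)


# ---------------------------------------------------------------------------
# shuffle-eigenvalue ensemble count
# ---------------------------------------------------------------------------


@dataclass
class EnsembleCountEstimate:
    """Number of covariance eigenvalues exceeding the shuffle null."""

    n_significant: int
    eigenvalues: np.ndarray  # sorted descending
    null_threshold: float
    n_shuffles: int
    percentile: float
    dropped_unit_ids: np.ndarray


def estimate_ensemble_count(
    m: GroomingMatrix,
    n_shuffles: int = 5000,
    rng: np.random.Generator | None = None,
    percentile: float = 99.0,
) -> EnsembleCountEstimate:
    """Shuffle-eigenvalue estimate of the number of ensembles.

    Each unit's binned activity (rates) is z-scored; the eigenvalues of the
    resulting unit-unit covariance (= correlation) matrix are compared with
    the distribution of the *maximum* eigenvalue over ``n_shuffles``
    independent per-unit permutations of the time bins.  The estimate is the
    number of real eigenvalues above the null's ``percentile``-th percentile.
    """
    rng = np.random.default_rng() if rng is None else rng
    # the shuffle null assumes exchangeable bins per unit; width-truncated
    # trailing bins carry inflated variance aligned across all units, so they
    # are excluded from the test (they remain in the matrix for clustering)
    X = np.asarray(m.rates, dtype=float)[:, ~m.partial_bin]
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need at least 2 units and 3 bins")
    sd = X.std(axis=1)
    keep = sd > 0
    dropped = m.unit_ids[~keep]
    if len(dropped):
        warnings.warn(
            f"dropped {len(dropped)} zero-variance units before the eigenvalue test",
            stacklevel=2,
        )
    X = X[keep]
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd[keep, None]
    B = Xz.shape[1]

    eig = np.linalg.eigvalsh(Xz @ Xz.T / B)[::-1]
    null_max = np.empty(n_shuffles)
    for s in range(n_shuffles):
        Xs = rng.permuted(Xz, axis=1)
        null_max[s] = np.linalg.eigvalsh(Xs @ Xs.T / B)[-1]
    thr = float(np.percentile(null_max, percentile))
    return EnsembleCountEstimate(
        n_significant=int(np.sum(eig > thr)),
        eigenvalues=eig,
        null_threshold=thr,
        n_shuffles=n_shuffles,
        percentile=percentile,
        dropped_unit_ids=dropped,
    )


# ---------------------------------------------------------------------------
# meta-k-means
# ---------------------------------------------------------------------------


@dataclass
class EnsembleAssignment:
    """Meta-k-means output: cluster label per unit (-1 = unassigned) plus the
    co-assignment frequency matrix."""

    unit_ids: np.ndarray
    labels: np.ndarray
    coassignment: np.ndarray
    k_init: int
    n_runs: int
    pair_threshold: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if np.any(self.labels >= 0) else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def cluster_sizes(self) -> np.ndarray:
        return np.array(
            [int(np.sum(self.labels == c)) for c in range(self.n_clusters)]
        )


def _mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    assigned = labels >= 0
    lab = labels[assigned]
    if len(np.unique(lab)) < 2:
        return np.nan
    return float(silhouette_score(X[assigned], lab, metric="euclidean"))


def meta_kmeans(
    m: GroomingMatrix,
    rng: np.random.Generator | None = None,
    n_runs: int = 1000,
    pair_threshold: float = 0.8,
    k_init: int | None = None,
) -> EnsembleAssignment:
    """Consensus clustering of units into ensembles.

    Runs ``n_runs`` repeats of k-means (greedy k-means++ initialization, one
    initialization per repeat) with units as the clustered items and time
    bins as their features.  The distance step operates on each unit's
    z-scored binned rates — the same standardized representation the
    eigenvalue test uses — so that two units are close exactly when their
    activity *co-fluctuates*.  (Min-max rows without standardization leave a
    residual rate-level continuum, and smoothing correlates neighbouring
    bins; both artifacts stabilize chance partitions of unstructured units
    across repeats and would let spurious clusters through the co-assignment
    threshold.)  The initial k is the rounded square root of the number of
    units.  Unit pairs co-assigned in more than ``pair_threshold`` of the
    runs define a graph whose connected components are the intermediate
    clusters (components of size 1 are unassigned); clusters are then
    greedily merged while the mean silhouette score over clustered units
    does not decrease.
    """
    rng = np.random.default_rng() if rng is None else rng
    R = np.asarray(m.rates, dtype=float)
    sd = R.std(axis=1)
    sd[sd == 0] = 1.0
    X = (R - R.mean(axis=1, keepdims=True)) / sd[:, None]
    n = X.shape[0]
    if n < 4:
        raise ValueError("meta-k-means requires at least 4 units")
    k = int(round(np.sqrt(n))) if k_init is None else k_init

    coassign = np.zeros((n, n))
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    for s in seeds:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-4,
            random_state=int(s),
        ).fit(X)
        onehot = np.eye(k, dtype=np.float64)[km.labels_]
        coassign += onehot @ onehot.T
    coassign /= n_runs
    np.fill_diagonal(coassign, 1.0)

    adj = csr_matrix((coassign > pair_threshold).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    labels = np.full(n, -1)
    next_label = 0
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) >= 2:
            labels[members] = next_label
            next_label += 1
    labels = _merge_by_silhouette(X, labels)
    return EnsembleAssignment(
        unit_ids=m.unit_ids,
        labels=labels,
        coassignment=coassign,
        k_init=k,
        n_runs=n_runs,
        pair_threshold=pair_threshold,
    )


def _merge_by_silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedily merge the cluster pair giving the highest mean silhouette,
    accepting merges while the score does not decrease.  Merging down to a
    single cluster is never evaluated (silhouette is undefined there)."""
    labels = labels.copy()
    while True:
        ids = np.unique(labels[labels >= 0])
        if len(ids) < 3:
            break
        current = _mean_silhouette(X, labels)
        best_score, best_pair = -np.inf, None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                trial = labels.copy()
                trial[trial == b] = a
                s = _mean_silhouette(X, trial)
                if s > best_score:
                    best_score, best_pair = s, (a, b)
        if best_pair is None or best_score < current:
            break
        a, b = best_pair
        labels[labels == b] = a
        logger.debug("merged clusters %s and %s (silhouette %.3f)", a, b, best_score)
    # relabel to consecutive ids ordered by first member for determinism
    out = np.full_like(labels, -1)
    next_label = 0
    seen = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            if lab not in seen:
                seen[lab] = next_label
                next_label += 1
            out[i] = seen[lab]
    return out
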