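"""Low-dimensional grooming trajectories via rank-3 NMF.

Non-negative matrix factorization of concatenated bout (±5 s) activity, run
separately on all units, clustered units, unclustered units, and ensemble
averages.  The factorization minimizes the Frobenius loss with multiplicative
updates from an NNDSVDa start (nonnegative double SVD with zeros filled with
the matrix mean), which makes the solve deterministic; the per-iteration loss
sequence is recorded and is non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GroomingBouts, SpikeData
from .ensembles import EnsembleAssignment, _bin_segments, _smooth_by_segment
from .synthetic import _merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryFactors",
    "TrajectoryInputs",
    "nndsvda_init",
    "nmf_trajectories",
    "split_trajectory_inputs",
]

#: Temporal resolution of the trajectory inputs (s); the smoothing sigma is
#: 0.5 s.  Chosen to keep inputs non-negative and comparable across units.
TRAJ_BIN_S = 0.25
TRAJ_SMOOTH_SIGMA_S = 0.5
TRAJ_PAD_S = 5.0

_EPS = 1e-12


@dataclass
class TrajectoryFactors:
    """NMF factors of one activity matrix.

    ``basis`` (rows x k) holds each unit's/ensemble's loading on the factors;
    ``scores`` (k x time) the factor time courses over the concatenated bout
    time.  Factors are ordered by the time of their peak score, so factor 1
    rises first (onset), factor 2 next (maintenance), factor 3 last (return).
    """

    basis: np.ndarray
    scores: np.ndarray
    bout_segmentation: np.ndarray
    reconstruction_error: float
    loss_history: np.ndarray
    converged: bool


def nndsvda_init(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization, zeros filled with mean(V)."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    m, n = V.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        x, y = U[:, j], Vt[j]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        np_norm, nn_norm = np.linalg.norm(xp) * np.linalg.norm(yp), np.linalg.norm(
            xn
        ) * np.linalg.norm(yn)
        if np_norm >= nn_norm:
            u, v, sig = xp, yp, np_norm
        else:
            u, v, sig = xn, yn, nn_norm
        if sig > 0:
            u = u / np.linalg.norm(u)
            v = v / np.linalg.norm(v)
            W[:, j] = np.sqrt(S[j] * sig) * u
            H[j] = np.sqrt(S[j] * sig) * v
    avg = V.mean()
    W[W == 0] = avg
    H[H == 0] = avg
    return W, H


def nmf_trajectories(
    activity: np.ndarray,
    k: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    bout_segmentation: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TrajectoryFactors:
    """Factorize a non-negative rows x time matrix into k components.

    Multiplicative updates minimize ``||V - W H||_F`` from the NNDSVDa start;
    iteration stops when the relative loss change drops below ``tol`` or
    after ``max_iter`` iterations.  ``rng`` is accepted for interface
    symmetry but unused: the initialization is deterministic.
    """
    V = np.asarray(activity, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be non-negative")
    if V.ndim != 2:
        raise ValueError("activity must be a 2-D matrix")
    if k > min(V.shape):
        raise ValueError("k exceeds the matrix rank bound min(rows, time)")
    W, H = nndsvda_init(V, k)
    norm_V = np.linalg.norm(V)
    loss = [np.linalg.norm(V - W @ H)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        loss.append(np.linalg.norm(V - W @ H))
        if abs(loss[-2] - loss[-1]) <= tol * max(loss[-2], _EPS):
            converged = True
            break
    # order factors by the time their score peaks (onset -> return)
    order = np.argsort([int(np.argmax(h)) for h in H], kind="stable")
    W, H = W[:, order], H[order]
    if bout_segmentation is None:
        bout_segmentation = np.zeros(V.shape[1], dtype=int)
    return TrajectoryFactors(
        basis=W,
        scores=H,
        bout_segmentation=np.asarray(bout_segmentation),
        reconstruction_error=float(loss[-1] / (norm_V + _EPS)),
        loss_history=np.asarray(loss),
        converged=converged,
    )


@dataclass
class TrajectoryInputs:
    """Row matrices sharing one concatenated-bout time base."""

    all_units: np.ndarray
    clustered_units: np.ndarray
    unclustered_units: np.ndarray
    ensemble_means: np.ndarray
    bout_segmentation: np.ndarray
    bin_start_times_s: np.ndarray
    bin_size_s: float


def split_trajectory_inputs(
    spikes: SpikeData,
    bouts: GroomingBouts,
    assignment: EnsembleAssignment,
    bin_size_s: float = TRAJ_BIN_S,
    smooth_sigma_s: float = TRAJ_SMOOTH_SIGMA_S,
    pad_s: float = TRAJ_PAD_S,
) -> TrajectoryInputs:
    """Build the four trajectory input matrices for one session.

    Activity during all padded (±5 s) bouts is concatenated at 250 ms bins,
    Gaussian-smoothed (σ = 0.5 s) within each bout segment, and min-max
    scaled per row, preserving non-negativity.  Empty subsets come back as
    0-row matrices with a warning.
    """
    if len(bouts) == 0:
        raise ValueError("at least one grooming bout required")
    padded = np.column_stack([bouts.starts - pad_s, bouts.ends + pad_s])
    segments = _merge_intervals(np.clip(padded, 0.0, spikes.duration_s))
    counts, starts, widths, seg_ids = _bin_segments(spikes.times, segments, bin_size_s)
    rates = counts / widths
    smoothed = _smooth_by_segment(rates, seg_ids, smooth_sigma_s / bin_size_s)
    lo = smoothed.min(axis=1, keepdims=True)
    hi = smoothed.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    rows = (smoothed - lo) / span

    labels = assignment.labels
    clustered = rows[labels >= 0]
    unclustered = rows[labels < 0]
    for name, mat in (("clustered", clustered), ("unclustered", unclustered)):
        if mat.shape[0] == 0:
            warnings.warn(f"{name} unit subset is empty", stacklevel=2)
    if assignment.n_clusters:
        ens = np.vstack(
            [
                rows[assignment.members(c)].mean(axis=0)
                for c in range(assignment.n_clusters)
            ]
        )
    else:
        warnings.warn("no ensembles; ensemble_means is empty", stacklevel=2)
        ens = np.empty((0, rows.shape[1]))
    return TrajectoryInputs(
        all_units=rows,
        clustered_units=clustered,
        unclustered_units=unclustered,
        ensemble_means=ens,
        bout_segmentation=seg_ids,
        bin_start_times_s=starts,
        bin_size_s=bin_size_s,
    )
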