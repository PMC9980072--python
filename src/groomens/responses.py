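"""Event-aligned single-unit analysis.

Spike binning, bout isolation, event-triggered averages around grooming
transitions, the 2-SD grooming-modulation flag, and PCA typing of
transition-aligned response profiles.

The 2-SD flag follows the published selection rule for display examples
(500 ms bins; start-aligned baseline 5-2 s before the bout vs a test window
from 1 s before to 1 s after the transition) and is exposed as a labelled
utility only — it does not gate any downstream stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import BinnedActivity, GroomingBouts, SpikeData

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseProfile",
    "PCATyping",
    "bin_spikes",
    "select_isolated_bouts",
    "event_triggered_average",
    "flag_grooming_modulated",
    "pca_response_types",
]


def bin_spikes(
    spikes: SpikeData, bin_size_s: float, t0: float, t1: float
) -> BinnedActivity:
    """Sum spike counts in non-overlapping half-open bins tiling [t0, t1).

    Bins are ``[t0 + k*bin, t0 + (k+1)*bin)``; a spike exactly at a bin edge
    lands in the right-hand bin.  A trailing partial bin (truncated at
    ``t1``) is kept, so summing over bins conserves the number of spikes in
    ``[t0, t1)``.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n_bins = int(np.ceil((t1 - t0) / bin_size_s - 1e-12))
    starts = t0 + bin_size_s * np.arange(n_bins)
    widths = np.minimum(starts + bin_size_s, t1) - starts
    counts = np.zeros((spikes.n_units, n_bins), dtype=np.int64)
    for i, t in enumerate(spikes.times):
        sel = t[(t >= t0) & (t < t1)]
        if len(sel):
            idx = np.floor((sel - t0) / bin_size_s).astype(int)
            np.add.at(counts[i], idx, 1)
    return BinnedActivity(
        unit_ids=spikes.unit_ids,
        bin_size_s=bin_size_s,
        bin_start_times_s=starts,
        counts=counts,
        bin_widths_s=widths,
    )


def select_isolated_bouts(
    bouts: GroomingBouts, min_gap_s: float = 10.0, min_start_s: float = 5.0
) -> GroomingBouts:
    """Keep bouts whose flanks are uncontaminated by a neighbouring bout.

    A bout is kept iff it starts at least ``min_gap_s`` after the end of the
    previous bout; the first bout needs ``min_start_s`` of clear session
    before it so the ±5 s flanks exist.  Bouts should have been merged with
    :func:`groomens.grooming.merge_close_bouts` (3 s rule) first.
    """
    iv = bouts.intervals
    if len(iv) == 0:
        return bouts
    keep = np.ones(len(iv), dtype=bool)
    keep[0] = iv[0, 0] >= min_start_s
    if len(iv) > 1:
        keep[1:] = (iv[1:, 0] - iv[:-1, 1]) >= min_gap_s
    return GroomingBouts(iv[keep])


@dataclass
class ResponseProfile:
    """Per-unit event-triggered average in a window around a transition."""

    unit_ids: np.ndarray
    alignment: str  # 'start' or 'end'
    window_s: tuple
    bin_size_s: float
    mean_response: np.ndarray  # units x bins
    n_bouts_used: int

    @property
    def n_bins(self) -> int:
        return self.mean_response.shape[1]

    @property
    def bin_offsets_s(self) -> np.ndarray:
        """Left edge of each bin relative to the event."""
        return self.window_s[0] + self.bin_size_s * np.arange(self.n_bins)


def _event_counts(
    t: np.ndarray, events: np.ndarray, offsets: np.ndarray, bin_size_s: float
) -> np.ndarray:
    """events x bins matrix of spike counts at given bin offsets."""
    out = np.empty((len(events), len(offsets)))
    for j, ev in enumerate(events):
        edges = ev + np.append(offsets, offsets[-1] + bin_size_s)
        idx = np.searchsorted(t, edges)
        out[j] = np.diff(idx)
    return out


def event_triggered_average(
    spikes: SpikeData,
    events,
    window_s: tuple = (-5.0, 5.0),
    bin_size_s: float = 0.25,
    alignment: str = "start",
) -> ResponseProfile:
    """Mean binned response of every unit aligned to a list of event times.

    The event time falls on a bin boundary (for the default ±5 s window at
    250 ms that is the boundary between bins 19 and 20).  Events closer than
    the window half-width (plus edge margin) to the session edges are dropped
    with a warning rather than zero-padded.
    """
    events = np.asarray(events, dtype=float)
    lo, hi = window_s
    ok = (events + lo >= 0.0) & (events + hi <= spikes.duration_s)
    if ok.sum() < len(events):
        warnings.warn(
            f"dropped {int((~ok).sum())} events too close to the session edges",
            stacklevel=2,
        )
    events = events[ok]
    if len(events) == 0:
        raise ValueError("no usable events for the event-triggered average")
    n_bins = int(round((hi - lo) / bin_size_s))
    offsets = lo + bin_size_s * np.arange(n_bins)
    mean = np.empty((spikes.n_units, n_bins))
    for i, t in enumerate(spikes.times):
        mean[i] = _event_counts(t, events, offsets, bin_size_s).mean(axis=0)
    return ResponseProfile(
        unit_ids=spikes.unit_ids,
        alignment=alignment,
        window_s=window_s,
        bin_size_s=bin_size_s,
        mean_response=mean,
        n_bouts_used=len(events),
    )


def flag_grooming_modulated(
    spike_times: np.ndarray,
    bouts: GroomingBouts,
    alignment: str = "start",
    bin_size_s: float = 0.5,
    n_sd: float = 2.0,
) -> bool:
    """2-SD grooming-modulation flag for a single unit.

    At 500 ms bins: for start alignment the baseline is the bout-averaged
    activity 5 to 2 s before bout start and the test window runs from 1 s
    before to 1 s after the start; for end alignment the baseline is 2 to 5 s
    after bout end with the same ±1 s test window.  The unit is flagged iff
    mean(test) > mean(baseline) + ``n_sd``·sd(baseline), where the mean and
    the sample standard deviation are taken over the bout-averaged baseline
    bins.  An all-zero baseline (sd = 0, mean = 0) degenerates to
    "any test activity at all".
    """
    if len(bouts) == 0:
        raise ValueError("at least one bout required")
    t = np.asarray(spike_times, dtype=float)
    if alignment == "start":
        events = bouts.starts
        base_w, test_w = (-5.0, -2.0), (-1.0, 1.0)
    elif alignment == "end":
        events = bouts.ends
        base_w, test_w = (2.0, 5.0), (-1.0, 1.0)
    else:
        raise ValueError("alignment must be 'start' or 'end'")

    def avg_bins(w):
        offs = np.arange(w[0], w[1] - 1e-9, bin_size_s)
        return _event_counts(t, events, offs, bin_size_s).mean(axis=0)

    base = avg_bins(base_w)
    test = avg_bins(test_w)
    m, sd = base.mean(), base.std(ddof=1)
    if sd == 0.0 and m == 0.0:
        logger.debug("all-zero baseline; degenerate flag rule applied")
        return bool(test.mean() > 0.0)
    return bool(test.mean() > m + n_sd * sd)


@dataclass
class PCATyping:
    """First-two-PC typing of transition-aligned response profiles."""

    unit_ids: np.ndarray
    components: np.ndarray  # 2 x time
    explained_variance_fraction: np.ndarray
    weights: np.ndarray  # units x 2
    group: np.ndarray  # 'PC1' / 'PC2' per unit
    sign: np.ndarray  # '+' / '-' per unit
    dropped_unit_ids: np.ndarray


def pca_response_types(profiles: ResponseProfile) -> PCATyping:
    """Type units by their first-two-PC weights on z-scored response profiles.

    Each unit's mean response is z-scored across time bins; PCA is run with
    units as observations and time bins as variables, so the components are
    time courses.  Units whose weight magnitude is larger on PC1 than PC2
    form the PC1 group, the rest the PC2 group, and the weight's sign splits
    each group into elevated/suppressed variants.  Component sign is fixed by
    orienting each component so its largest-|value| time bin is positive,
    which makes group counts reproducible across runs.  Constant (zero
    variance) rows cannot be z-scored and are dropped with a warning.
    """
    X = np.asarray(profiles.mean_response, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("at least 3 units required for PCA typing")
    sd = X.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropped {int((~keep).sum())} constant-response units before PCA",
            stacklevel=2,
        )
    Xz = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]

    pca = PCA(n_components=2, svd_solver="full")
    w = pca.fit_transform(Xz)  # units x 2
    comps = pca.components_.copy()  # 2 x bins
    for c in range(2):
        peak = np.argmax(np.abs(comps[c]))
        if comps[c, peak] < 0:
            comps[c] *= -1.0
            w[:, c] *= -1.0

    pc1 = np.abs(w[:, 0]) >= np.abs(w[:, 1])
    group = np.where(pc1, "PC1", "PC2")
    chosen = np.where(pc1, w[:, 0], w[:, 1])
    sign = np.where(chosen >= 0, "+", "-")
    return PCATyping(
        unit_ids=profiles.unit_ids[keep],
        components=comps,
        explained_variance_fraction=pca.explained_variance_ratio_,
        weights=w,
        group=group,
        sign=sign,
        dropped_unit_ids=profiles.unit_ids[~keep],
    )
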