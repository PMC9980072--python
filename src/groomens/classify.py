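"""Putative cell-type classification of sorted striatal units.

Units are labelled putative SPN (spiny projection neuron), FSI (fast-spiking
interneuron), or 'other' from two waveform features and the mean firing rate
over the entire session:

* SPN  iff peak width > 150 us AND peak-valley interval > 500 us AND rate <= 10 Hz
* FSI  iff peak width <= 150 us AND peak-valley interval <= 500 us AND rate >= 0.1 Hz
* otherwise 'other' (excluded from all downstream analyses)

The boundary operators are exactly as printed above: a 150 us width is
FSI-side, a 10 Hz rate is SPN-side.  Peak width is measured as the full width
at half maximum of the dominant deflection of the mean waveform, and the
peak-valley interval as the time from the dominant extremum to the subsequent
opposite-sign extremum; both definitions are standard and isolated behind
:func:`extract_waveform_features` so alternatives can be swapped in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SPN_MIN_WIDTH_US",
    "SPN_MIN_PV_US",
    "SPN_MAX_RATE_HZ",
    "FSI_MIN_RATE_HZ",
    "extract_waveform_features",
    "classify_unit",
    "classify_units",
]

SPN_MIN_WIDTH_US = 150.0
SPN_MIN_PV_US = 500.0
SPN_MAX_RATE_HZ = 10.0
FSI_MIN_RATE_HZ = 0.1


def _half_crossing(w: np.ndarray, i_from: int, i_to: int, half: float, step: int) -> float:
    """Fractional sample index where |w| crosses |half| moving from the
    extremum at ``i_from`` toward ``i_to`` in direction ``step``; clips to the
    waveform edge if the deflection never falls below half maximum."""
    sign = np.sign(half)
    prev = i_from
    for j in range(i_from + step, i_to + step, step):
        if sign * w[j] <= sign * half:
            # linear interpolation between prev and j
            frac = (sign * w[prev] - sign * half) / (sign * w[prev] - sign * w[j])
            return prev + step * frac
        prev = j
    return float(i_to)


def extract_waveform_features(
    mean_waveform: np.ndarray, sampling_rate_hz: float
) -> tuple[float, float]:
    """Measure (peak_width_us, peak_valley_us) from a mean waveform.

    Peak width: full width at half maximum of the dominant (largest |value|)
    deflection, with linear interpolation at the half-max crossings.
    Peak-valley: time from the dominant extremum to the subsequent
    opposite-sign extremum.
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.ndim != 1 or len(w) < 3:
        raise ValueError("mean waveform must be a 1-D array of length >= 3")
    d = np.diff(w)
    if np.all(d >= 0) or np.all(d <= 0):
        raise ValueError("monotone waveform: no extremum to measure")

    i0 = int(np.argmax(np.abs(w)))
    half = w[i0] / 2.0
    left = _half_crossing(w, i0, 0, half, -1)
    right = _half_crossing(w, i0, len(w) - 1, half, +1)
    dt_us = 1e6 / sampling_rate_hz
    peak_width_us = (right - left) * dt_us

    tail = w[i0 + 1 :]
    if len(tail) == 0:
        raise ValueError("dominant extremum at the last sample: no subsequent extremum")
    j = int(np.argmax(tail)) if w[i0] < 0 else int(np.argmin(tail))
    peak_valley_us = (j + 1) * dt_us
    return float(peak_width_us), float(peak_valley_us)


def classify_unit(peak_width_us: float, peak_valley_us: float, mean_rate_hz: float) -> str:
    """Label one unit 'SPN', 'FSI', or 'other' from its features."""
    for v in (peak_width_us, peak_valley_us, mean_rate_hz):
        if not np.isfinite(v):
            raise ValueError("waveform features and rate must be finite")
    if (
        peak_width_us > SPN_MIN_WIDTH_US
        and peak_valley_us > SPN_MIN_PV_US
        and mean_rate_hz <= SPN_MAX_RATE_HZ
    ):
        return "SPN"
    if (
        peak_width_us <= SPN_MIN_WIDTH_US
        and peak_valley_us <= SPN_MIN_PV_US
        and mean_rate_hz >= FSI_MIN_RATE_HZ
    ):
        return "FSI"
    return "other"


def classify_units(units: pd.DataFrame) -> pd.Series:
    """Vectorised classification of a unit feature table.

    Expects columns ``peak_width_us``, ``peak_valley_us``, ``mean_rate_hz``;
    returns a 'label' Series aligned to the table's index.
    """
    labels = [
        classify_unit(r.peak_width_us, r.peak_valley_us, r.mean_rate_hz)
        for r in units.itertuples()
    ]
    return pd.Series(labels, index=units.index, name="label")
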