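"""Binning, bout isolation, event-triggered averages, 2-SD flag, PCA typing."""

import numpy as np
import pytest

from groomens import (
    GroomingBouts,
    SpikeData,
    bin_spikes,
    event_triggered_average,
    flag_grooming_modulated,
    pca_response_types,
    select_isolated_bouts,
)
from groomens.responses import ResponseProfile


def _spikes(times_per_unit, duration=100.0):
    return SpikeData(np.arange(len(times_per_unit)), times_per_unit, duration)


class TestBinning:
    def test_all_spikes_in_first_bin(self):
        s = _spikes([np.full(10, 0.1)])
        b = bin_spikes(s, 0.5, 0.0, 5.0)
        assert b.counts[0, 0] == 10
        assert b.counts[0, 1:].sum() == 0

    def test_total_count_conserved(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        s = _spikes([t])
        b = bin_spikes(s, 0.5, 0.0, 100.0)
        assert b.counts.sum() == 500

    def test_edge_spike_lands_in_right_bin(self):
        s = _spikes([np.array([1.0])])
        b = bin_spikes(s, 0.5, 0.0, 5.0)
        assert b.counts[0, 2] == 1  # bin [1.0, 1.5)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            bin_spikes(_spikes([np.array([])]), 0.5, 5.0, 5.0)


class TestIsolation:
    def test_bout_within_ten_seconds_dropped(self):
        b = GroomingBouts.from_pairs([(90, 100), (105, 110)])
        out = select_isolated_bouts(b)
        np.testing.assert_allclose(out.intervals, [[90, 100]])

    def test_large_gaps_unchanged(self):
        b = GroomingBouts.from_pairs([(20, 30), (50, 60), (80, 90)])
        assert len(select_isolated_bouts(b)) == 3

    def test_first_bout_needs_leading_margin(self):
        b = GroomingBouts.from_pairs([(2, 10)])
        assert len(select_isolated_bouts(b)) == 0


class TestEventTriggeredAverage:
    def test_single_event_equals_binned_counts(self, rng):
        t = np.sort(rng.uniform(0, 100, 300))
        s = _spikes([t])
        prof = event_triggered_average(s, [50.0])
        edges = 50.0 + np.arange(-5.0, 5.01, 0.25)
        expected = np.histogram(t, bins=edges)[0]
        np.testing.assert_array_equal(prof.mean_response[0], expected)

    def test_event_maps_to_bin_boundary_19_20(self):
        # one spike just after the event lands in bin 20, just before in bin 19
        s = _spikes([np.array([49.999, 50.001])])
        prof = event_triggered_average(s, [50.0])
        assert prof.mean_response[0, 19] == 1
        assert prof.mean_response[0, 20] == 1

    def test_poisson_unit_flat_profile(self, rng):
        t = np.sort(rng.uniform(0, 2000, 2000 * 5))  # ~5 Hz
        s = _spikes([t], duration=2000.0)
        events = np.arange(50.0, 1950.0, 40.0)
        prof = event_triggered_average(s, events)
        expected = 5 * 0.25
        assert np.allclose(prof.mean_response[0].mean(), expected, rtol=0.1)
        assert prof.mean_response[0].std() < 0.5 * expected

    def test_edge_events_dropped_with_warning(self):
        s = _spikes([np.array([10.0])])
        with pytest.warns(UserWarning, match="dropped"):
            prof = event_triggered_average(s, [2.0, 50.0])
        assert prof.n_bouts_used == 1

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            event_triggered_average(_spikes([np.array([1.0])]), [])


def _brute_force_flag(spike_times, bouts, alignment):
    """Independent re-derivation of the 2-SD rule from raw spike times."""
    events = bouts.starts if alignment == "start" else bouts.ends
    if alignment == "start":
        base_offs = [-5.0, -4.5, -4.0, -3.5, -3.0, -2.5]
    else:
        base_offs = [2.0, 2.5, 3.0, 3.5, 4.0, 4.5]
    test_offs = [-1.0, -0.5, 0.0, 0.5]

    def counts(offs):
        return np.array(
            [
                [np.sum((spike_times >= e + o) & (spike_times < e + o + 0.5))
                 for e in events]
                for o in offs
            ]
        ).mean(axis=1)

    base, test = counts(base_offs), counts(test_offs)
    m, sd = base.mean(), base.std(ddof=1)
    if sd == 0 and m == 0:
        return test.mean() > 0
    return test.mean() > m + 2 * sd


class TestModulationFlag:
    def test_constant_rate_not_flagged(self):
        # perfectly regular spiking: identical counts in every bin
        t = np.arange(0.05, 200.0, 0.1)
        bouts = GroomingBouts.from_pairs([(50, 60), (100, 112), (150, 165)])
        assert flag_grooming_modulated(t, bouts, "start") is False
        assert flag_grooming_modulated(t, bouts, "end") is False

    def test_silent_unit_not_flagged(self):
        bouts = GroomingBouts.from_pairs([(50, 60)])
        assert flag_grooming_modulated(np.array([]), bouts, "start") is False

    def test_planted_step_up_flagged(self, rng):
        bouts = GroomingBouts.from_pairs([(50, 62), (150, 165), (260, 270)])
        base, gain = 4.0, 10.0
        t = np.sort(rng.uniform(0, 400, int(400 * base)))
        extra = np.concatenate(
            [rng.uniform(s, e, int((e - s) * base * (gain - 1))) for s, e in bouts]
        )
        t = np.sort(np.concatenate([t, extra]))
        assert flag_grooming_modulated(t, bouts, "start") is True

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n_bouts = rng.integers(1, 4)
            starts = np.sort(rng.uniform(20, 150, n_bouts))
            starts = starts[np.r_[True, np.diff(starts) > 25]]
            bouts = GroomingBouts.from_pairs(
                [(s, s + rng.uniform(5, 12)) for s in starts]
            )
            t = np.sort(rng.uniform(0, 200, rng.integers(0, 400)))
            for alignment in ("start", "end"):
                assert flag_grooming_modulated(t, bouts, alignment) == bool(
                    _brute_force_flag(t, bouts, alignment)
                )


class TestPCATyping:
    def _profile(self, X):
        return ResponseProfile(
            unit_ids=np.arange(len(X)),
            alignment="start",
            window_s=(-5.0, 5.0),
            bin_size_s=0.25,
            mean_response=np.asarray(X, float),
            n_bouts_used=10,
        )

    def test_mirrored_pair_opposite_weights(self, rng):
        base = rng.normal(size=40)
        X = np.vstack(
            [base + 0.01 * rng.normal(size=40) for _ in range(5)]
            + [-base + 0.01 * rng.normal(size=40) for _ in range(5)]
        )
        typ = pca_response_types(self._profile(X))
        w1 = typ.weights[:, 0]
        assert np.all(w1[:5] * w1[5:] < 0)
        assert np.allclose(np.abs(w1[:5]).mean(), np.abs(w1[5:]).mean(), rtol=0.05)

    def test_explained_variance_valid(self, rng):
        X = rng.normal(size=(30, 40))
        typ = pca_response_types(self._profile(X))
        ev = typ.explained_variance_fraction
        assert np.all((0 <= ev) & (ev <= 1)) and ev[0] >= ev[1]

    def test_constant_row_dropped_with_warning(self, rng):
        X = rng.normal(size=(5, 40))
        X[2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            typ = pca_response_types(self._profile(X))
        assert 2 in typ.dropped_unit_ids
        assert len(typ.unit_ids) == 4

    def test_component_orientation_deterministic(self, rng):
        X = rng.normal(size=(20, 40))
        t1 = pca_response_types(self._profile(X))
        t2 = pca_response_types(self._profile(X))
        np.testing.assert_allclose(t1.components, t2.components)
        for c in range(2):
            peak = np.argmax(np.abs(t1.components[c]))
            assert t1.components[c, peak] > 0

    def test_step_vs_transient_groups_recovered(self, rng):
        step = np.r_[np.zeros(20), np.ones(20)]
        bump = np.r_[np.zeros(16), np.ones(8), np.zeros(16)]
        rows = (
            [+step + 0.15 * rng.normal(size=40) for _ in range(25)]
            + [-step + 0.15 * rng.normal(size=40) for _ in range(25)]
            + [+bump + 0.15 * rng.normal(size=40) for _ in range(25)]
            + [-bump + 0.15 * rng.normal(size=40) for _ in range(25)]
        )
        typ = pca_response_types(self._profile(np.vstack(rows)))
        group = typ.group
        acc = (np.mean(group[:50] == "PC1") + np.mean(group[50:] == "PC2")) / 2
        assert acc >= 0.9

    def test_fewer_than_three_units_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_response_types(self._profile(rng.normal(size=(2, 40))))
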