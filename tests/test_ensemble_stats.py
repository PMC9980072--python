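"""AUC, correlation/distance splits, time warping, bootstrap bands, summaries."""

import numpy as np
import pytest

from groomens import (
    GroomingBouts,
    SpikeData,
    bootstrap_null,
    build_grooming_matrix,
    cluster_summary,
    distribution_auc,
    ensemble_peak_times,
    fraction_active_units,
    pairwise_correlation_split,
    pairwise_distance_split,
    timewarp_bout_activity,
)
from groomens.ensembles import EnsembleAssignment
from groomens.ensemble_stats import band_escape_runs, cumulative_curves


def _assignment(labels):
    labels = np.asarray(labels)
    n = len(labels)
    return EnsembleAssignment(
        unit_ids=np.arange(n), labels=labels, coassignment=np.eye(n),
        k_init=0, n_runs=0, pair_threshold=0.8,
    )


class TestAUC:
    def test_identical_distributions(self):
        x = [1.0, 2.0, 3.0]
        assert distribution_auc(x, x) == pytest.approx(0.5)

    def test_complete_separation(self):
        assert distribution_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert distribution_auc([0.1, 0.2], [0.9, 0.8]) == 0.0

    def test_complement_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(0.5, 1, size=15)
        assert distribution_auc(x, y) == pytest.approx(1 - distribution_auc(y, x))

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(100):
            x = rng.integers(0, 8, rng.integers(1, 10)).astype(float)
            y = rng.integers(0, 8, rng.integers(1, 10)).astype(float)
            wins = sum(
                1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y
            )
            assert distribution_auc(x, y) == pytest.approx(wins / (len(x) * len(y)))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_auc([], [1.0])


class TestCorrelationSplit:
    def test_identical_rows_give_unit_within_correlation(self, rng):
        rows = rng.normal(size=(4, 50))
        rows[1] = rows[0]
        within, between = pairwise_correlation_split(rows, [0, 0, -1, -1])
        assert pytest.approx(1.0) in within.tolist()
        assert len(within) == 1 and len(between) == 5

    def test_pair_counts_add_up(self, rng):
        n = 8
        rows = rng.normal(size=(n, 30))
        within, between = pairwise_correlation_split(
            rows, [0, 0, 0, 1, 1, -1, -1, -1]
        )
        assert len(within) + len(between) == n * (n - 1) // 2
        assert len(within) == 3 + 1

    def test_zero_variance_unit_skipped(self, rng):
        rows = rng.normal(size=(4, 30))
        rows[2] = 1.0
        within, between = pairwise_correlation_split(rows, [0, 0, 0, -1])
        assert len(within) + len(between) == 3  # pairs among the 3 varying units


class TestDistanceSplit:
    def test_colocated_and_adjacent_shank_distances(self):
        pos = np.array([[0.0, 100.0], [0.0, 100.0], [200.0, 100.0]])
        within, between = pairwise_distance_split(pos, [0, 0, -1])
        assert within.tolist() == [0.0]
        assert sorted(between.tolist()) == [200.0, 200.0]

    def test_missing_position_skipped(self):
        pos = np.array([[0.0, 0.0], [np.nan, 0.0], [0.0, 300.0]])
        within, between = pairwise_distance_split(pos, [0, 0, 0])
        assert len(within) == 1 and within[0] == 300.0

    def test_cumulative_curves_monotone(self, rng):
        grid = np.linspace(0, 600, 50)
        mean, sem_ = cumulative_curves(
            [rng.uniform(0, 600, 40) for _ in range(4)], grid
        )
        assert np.all(np.diff(mean) >= 0)
        assert mean[-1] == pytest.approx(1.0)
        assert np.all(sem_ >= 0)


def _matrix_for_warp(rng, bout=(50.0, 62.5), n_units=30, duration=200.0):
    times = [np.sort(rng.uniform(0, duration, 800)) for _ in range(n_units)]
    s = SpikeData(np.arange(n_units), times, duration)
    return build_grooming_matrix(s, GroomingBouts.from_pairs([bout]))


class TestWarp:
    def test_constant_core_stays_constant(self, rng):
        gm = _matrix_for_warp(rng)
        rows = np.full((1, gm.n_bins), 0.7)
        w = timewarp_bout_activity(gm, rows, target_len_bins=12)
        np.testing.assert_allclose(w.data, 0.7)

    def test_identity_when_core_already_target_length(self, rng):
        gm = _matrix_for_warp(rng)  # 15 bins: 3 + 9 + 3
        rows = rng.uniform(size=(2, gm.n_bins))
        w = timewarp_bout_activity(gm, rows, target_len_bins=9)
        np.testing.assert_allclose(w.data[0], rows)

    def test_linear_ramp_maps_to_linear_ramp(self, rng):
        gm = _matrix_for_warp(rng)
        rows = np.zeros((1, gm.n_bins))
        rows[0, 3:12] = np.linspace(0.0, 1.0, 9)
        w = timewarp_bout_activity(gm, rows, target_len_bins=25)
        core = w.data[0, 0, 3:28]
        np.testing.assert_allclose(core, np.linspace(0.0, 1.0, 25), atol=1e-12)

    def test_flanks_copied_unwarped(self, rng):
        gm = _matrix_for_warp(rng)
        rows = rng.uniform(size=(1, gm.n_bins))
        w = timewarp_bout_activity(gm, rows, target_len_bins=30)
        np.testing.assert_allclose(w.data[0, 0, :3], rows[0, :3])
        np.testing.assert_allclose(w.data[0, 0, -3:], rows[0, -3:])

    def test_monotone_trace_extremes_preserved(self, rng):
        gm = _matrix_for_warp(rng)
        rows = np.sort(rng.uniform(size=(1, gm.n_bins)), axis=1)
        w = timewarp_bout_activity(gm, rows, target_len_bins=40)
        core_in = rows[0, 3:12]
        core_out = w.data[0, 0, 3:43]
        assert core_out.min() == pytest.approx(core_in.min())
        assert core_out.max() == pytest.approx(core_in.max())


class TestBootstrap:
    def test_band_ordering_and_determinism(self, rng):
        duration = 1000.0
        times = [np.sort(rng.uniform(0, duration, 4000)) for _ in range(4)]
        s = SpikeData(np.arange(4), times, duration)
        norm_min = np.zeros(4)
        norm_max = np.full(4, 4.0)
        kw = dict(bout_duration_pool=[10.0, 14.0, 20.0], norm_min=norm_min,
                  norm_max=norm_max, target_len_bins=8, n_windows=100)
        n1 = bootstrap_null(s, rng=np.random.default_rng(3), **kw)
        n2 = bootstrap_null(s, rng=np.random.default_rng(3), **kw)
        assert np.all(n1.p_low <= n1.p_high)
        assert np.all(n1.p_low <= n1.mean + 1e-12)
        np.testing.assert_allclose(n1.mean, n2.mean)

    def test_empty_duration_pool_rejected(self, rng):
        s = SpikeData([0], [np.array([1.0])], 100.0)
        with pytest.raises(ValueError):
            bootstrap_null(s, [], np.zeros(1), np.ones(1), 5, n_windows=2, rng=rng)

    def test_escape_run_lengths(self):
        null = type("N", (), {})()
        null.p_low = np.zeros(10)
        null.p_high = np.ones(10)
        obs = np.array([0.5, 2.0, 2.0, 0.5, 2.0, 0.5, -1.0, -1.0, -1.0, 0.5])
        assert band_escape_runs(obs, null).tolist() == [2, 1, 3]


class TestPeaksAndFractions:
    def test_peak_of_constant_trace_is_bin_zero(self):
        assert ensemble_peak_times(np.ones((1, 12)))[0] == 0

    def test_peak_position(self):
        tr = np.zeros(20)
        tr[13] = 2.0
        assert ensemble_peak_times(tr[None, :])[0] == 13

    def test_fraction_active(self, rng):
        gm = _matrix_for_warp(rng, n_units=30)
        gm.counts[:, :] = 0
        gm.counts[0, 0] = 3
        gm.counts[1, 0] = 1
        a = _assignment([0, 0, 0, 0] + [-1] * 26)
        frac = fraction_active_units(gm, a)
        assert frac[0, 0] == pytest.approx(0.5)  # 2 of 4 members active
        assert frac[0, 1:].max() == 0.0


class TestClusterSummary:
    def test_regressions_on_degenerate_patterns(self):
        sessions = []
        for n_units, n_clusters in ((30, 2), (40, 2), (50, 2), (60, 2)):
            labels = np.full(n_units, -1)
            for c in range(n_clusters):
                labels[2 * c : 2 * c + 2] = c
            sessions.append((_assignment(labels), np.array(["SPN"] * n_units)))
        table, fits = cluster_summary(sessions)
        assert fits["clusters_vs_units"]["r2"] == pytest.approx(0.0)
        assert (table["spn_only"] == 2).all()

    def test_perfect_linear_relationship(self):
        sessions = []
        for n_units in (30, 40, 50, 60):
            n_clusters = n_units // 10
            labels = np.full(n_units, -1)
            for c in range(n_clusters):
                labels[2 * c : 2 * c + 2] = c
            sessions.append((_assignment(labels), np.array(["SPN"] * n_units)))
        _, fits = cluster_summary(sessions)
        assert fits["clusters_vs_units"]["r2"] == pytest.approx(1.0)
        assert fits["clusters_vs_units"]["p"] < 0.05

    def test_requires_two_sessions(self):
        with pytest.raises(ValueError):
            cluster_summary([(_assignment([0, 0]), np.array(["SPN", "SPN"]))])

    def test_composition_counts(self):
        labels = np.array([0, 0, 1, 1, 2, 2, -1])
        kinds = np.array(["SPN", "SPN", "FSI", "FSI", "SPN", "FSI", "SPN"])
        table, _ = cluster_summary(
            [(_assignment(labels), kinds), (_assignment(labels), kinds)]
        )
        row = table.iloc[0]
        assert (row["spn_only"], row["fsi_only"], row["mixed"]) == (1, 1, 1)
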