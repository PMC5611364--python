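"""Event-size distributions, deviation index, threshold synchrony."""

import numpy as np
import pytest

from burstsync.events import (
    deviation_index,
    event_size_distribution,
    threshold_synchrony,
    window_spike_counts,
)
from burstsync.raster import SpikeTrain
from burstsync.segmentation import ActivePeriodSet
from burstsync.validation import _naive_window_counts


def _units_from_times(times_per_unit, duration):
    return [
        SpikeTrain(f"u{i}", np.array(sorted(t), np.int64), "L2_4", "single", duration)
        for i, t in enumerate(times_per_unit)
    ]


class TestWindowCounts:
    def test_simultaneous_spikes_counted_in_covering_windows(self):
        units = _units_from_times([[50]] * 12, 200)
        periods = ActivePeriodSet(np.array([[0, 200]]), 200)
        counts = window_spike_counts(units, periods, 20)
        part = (counts > 0).sum(axis=0)
        # windows [31..50] cover t=50
        assert part.max() == 12
        assert (part == 12).sum() == 20

    def test_silent_raster_has_no_events(self):
        units = _units_from_times([[]] * 3, 500)
        periods = ActivePeriodSet(np.array([[0, 500]]), 500)
        counts = window_spike_counts(units, periods, 20)
        assert counts.sum() == 0

    def test_matches_naive_oracle(self, rng):
        units = _units_from_times(
            [np.unique(rng.integers(0, 200, size=25)) for _ in range(5)], 200
        )
        periods = ActivePeriodSet(np.array([[10, 90], [120, 200]]), 200)
        fast = window_spike_counts(units, periods, 20, 1)
        naive = _naive_window_counts(units, periods, 20, 1)
        assert np.array_equal(fast, naive)

    def test_windows_straddling_boundaries_excluded(self):
        units = _units_from_times([[95]], 200)
        periods = ActivePeriodSet(np.array([[90, 100]]), 200)  # too short for 20 ms
        assert window_spike_counts(units, periods, 20).shape[1] == 0


class TestSizeProbability:
    def test_hand_enumerated_probabilities(self):
        # 3 units, one active period [0, 40): window 20, step 20 -> 2 windows
        units = _units_from_times([[5, 25], [6], [7, 26]], 40)
        periods = ActivePeriodSet(np.array([[0, 40]]), 40)
        counts = window_spike_counts(units, periods, 20, step_ms=20)
        dist = event_size_distribution(units, periods, 20, counts=counts)
        # window 0: units {0,1,2} (3 spikes) -> size 3; window 1: {0,2} -> size 2
        assert dist.probabilities[3] == pytest.approx(0.5)
        assert dist.probabilities[2] == pytest.approx(0.5)

    def test_single_spike_windows_register_no_event(self):
        units = _units_from_times([[5], []], 20)
        periods = ActivePeriodSet(np.array([[0, 20]]), 20)
        counts = window_spike_counts(units, periods, 20, step_ms=20)
        dist = event_size_distribution(units, periods, 20, counts=counts)
        assert all(v == 0 for v in dist.probabilities.values())

    def test_subsample_repeat_count(self, rng):
        units = _units_from_times(
            [np.unique(rng.integers(0, 2_000, size=40)) for _ in range(15)], 2_000
        )
        periods = ActivePeriodSet(np.array([[0, 2_000]]), 2_000)
        dist = event_size_distribution(units, periods, 20, subsample_size=12,
                                       n_subsample_repeats=20, rng=rng)
        assert dist.n_subsample_repeats == 20
        assert max(dist.probabilities) <= 12

    def test_exactly_twelve_units_single_pass(self, rng):
        units = _units_from_times(
            [np.unique(rng.integers(0, 1_000, size=30)) for _ in range(12)], 1_000
        )
        periods = ActivePeriodSet(np.array([[0, 1_000]]), 1_000)
        dist = event_size_distribution(units, periods, 20, rng=rng)
        assert dist.n_subsample_repeats == 1

    def test_probability_sum_bounded_and_relabel_invariant(self, rng):
        times = [np.unique(rng.integers(0, 3_000, size=60)) for _ in range(6)]
        periods = ActivePeriodSet(np.array([[0, 3_000]]), 3_000)
        a = event_size_distribution(_units_from_times(times, 3_000), periods, 20)
        b = event_size_distribution(_units_from_times(times[::-1], 3_000), periods, 20)
        assert sum(a.probabilities.values()) <= 1.0 + 1e-12
        assert a.probabilities == b.probabilities


class TestDeviationIndex:
    def test_equal_distributions_give_zero(self):
        d = deviation_index({2: 0.1, 3: 0.02}, {2: 0.1, 3: 0.02})
        assert (d == 0).all()

    def test_null_absent_gives_plus_one(self):
        assert deviation_index({4: 0.01}, {4: 0.0})[4] == 1.0

    def test_observed_absent_gives_minus_one(self):
        assert deviation_index({4: 0.0}, {4: 0.005})[4] == -1.0

    def test_both_zero_undefined(self):
        assert np.isnan(deviation_index({5: 0.0}, {5: 0.0})[5])

    def test_bounded(self, rng):
        a = {k: float(rng.random()) for k in range(2, 10)}
        b = {k: float(rng.random()) for k in range(2, 10)}
        d = deviation_index(a, b)
        assert ((d >= -1) & (d <= 1)).all()


class TestThresholdSynchrony:
    def test_fully_synchronous_raster(self):
        units = _units_from_times([list(range(5, 2_000, 20))] * 8, 2_000)
        periods = ActivePeriodSet(np.array([[0, 2_000]]), 2_000)
        p = threshold_synchrony(units, periods, 20, 0.25)
        assert p == 1.0

    def test_silent_raster(self):
        units = _units_from_times([[]] * 8, 2_000)
        periods = ActivePeriodSet(np.array([[0, 2_000]]), 2_000)
        assert threshold_synchrony(units, periods, 20, 0.25) == 0.0

    def test_matches_brute_force_fraction(self, rng):
        times = [np.unique(rng.integers(0, 2_000, size=80)) for _ in range(8)]
        units = _units_from_times(times, 2_000)
        periods = ActivePeriodSet(np.array([[0, 2_000]]), 2_000)
        p = threshold_synchrony(units, periods, 20, 0.25)
        hits = total = 0
        for b in range(0, 2_000, 20):
            c = [np.sum((t >= b) & (t < b + 20)) for t in times]
            total += 1
            if sum(c) > 1 and sum(x > 0 for x in c) / 8 > 0.25:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_inclusive_threshold_for_half_participation(self):
        # exactly 50% of units active: counted only in inclusive mode
        units = _units_from_times([[10], [12], [], []], 100)
        periods = ActivePeriodSet(np.array([[0, 100]]), 100)
        strict = threshold_synchrony(units, periods, 100, 0.5, inclusive=False)
        inclusive = threshold_synchrony(units, periods, 100, 0.5, inclusive=True)
        assert strict == 0.0 and inclusive == 1.0
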