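"""Jitter and raster-marginal null models."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from burstsync.raster import BinnedRaster, SpikeTrain, write_spike_table
from burstsync.segmentation import ActivePeriodSet
from burstsync.surrogates import (
    SurrogateSpec,
    jitter_spikes,
    raster_marginal_shuffle,
    surrogate_ensemble,
)


def _one_period(duration=100_000):
    return ActivePeriodSet(np.array([[0, duration]]), duration)


class TestJitter:
    def test_tiny_halfwidth_barely_moves_spikes(self, rng):
        t = np.sort(rng.integers(100, 9_900, size=50))
        u = SpikeTrain("u", t, "L2_4", "single", 10_000)
        jit = jitter_spikes([u], _one_period(10_000),
                            SurrogateSpec("jitter", jitter_halfwidth=1), rng=rng)
        assert np.abs(np.sort(jit[0].spike_times) - t).max() <= 1

    def test_counts_conserved_and_support_respected(self, toy_units, toy_periods, rng):
        inside = [
            u.with_times(u.spike_times[toy_periods.contains(u.spike_times)])
            for u in toy_units
        ]
        jit = jitter_spikes(inside, toy_periods, SurrogateSpec("jitter"), rng=rng)
        for u, j in zip(inside, jit):
            assert j.n_spikes == u.n_spikes
            assert toy_periods.contains(j.spike_times).all()

    def test_spike_outside_active_periods_is_an_error(self):
        u = SpikeTrain("u", np.array([5_000]), "L2_4", "single", 10_000)
        periods = ActivePeriodSet(np.array([[0, 1_000]]), 10_000)
        with pytest.raises(ValueError, match="outside"):
            jitter_spikes([u], periods, SurrogateSpec("jitter"))

    def test_outside_keep_policy_leaves_stray_spikes(self, rng):
        u = SpikeTrain("u", np.array([500, 5_000]), "L2_4", "single", 10_000)
        periods = ActivePeriodSet(np.array([[0, 1_000]]), 10_000)
        jit = jitter_spikes([u], periods, SurrogateSpec("jitter"), rng=rng,
                            outside="keep")
        assert 5_000 in jit[0].spike_times
        assert jit[0].n_spikes == 2

    def test_displacement_distribution_uniform(self, rng):
        # all spikes at one interior time: the jittered positions are the
        # displacements themselves and should follow U(-1000, 1000)
        u = SpikeTrain("u", np.full(4_000, 50_000), "L2_4", "single", 100_000)
        spec = SurrogateSpec("jitter", jitter_halfwidth=1_000)
        jit = jitter_spikes([u], _one_period(), spec, rng=rng)
        disp = jit[0].spike_times - 50_000
        assert disp.min() >= -1_000 and disp.max() <= 1_000
        stat = kstest(disp, "uniform", args=(-1_000, 2_001))
        assert stat.pvalue > 0.01

    def test_deterministic_given_seed(self, toy_units, toy_periods):
        inside = [
            u.with_times(u.spike_times[toy_periods.contains(u.spike_times)])
            for u in toy_units
        ]
        a = jitter_spikes(inside, toy_periods, SurrogateSpec("jitter", seed=5))
        b = jitter_spikes(inside, toy_periods, SurrogateSpec("jitter", seed=5))
        for x, y in zip(a, b):
            assert np.array_equal(x.spike_times, y.spike_times)


class TestRasterMarginal:
    def test_marginals_conserved_exactly(self, rng):
        mat = (rng.random((8, 40)) < 0.3).astype(np.uint8)
        raster = BinnedRaster(mat, 20)
        groups = {u: ("L2_4" if i < 4 else "L5_6") for i, u in enumerate(raster.unit_ids)}
        shuf = raster_marginal_shuffle(raster, groups, SurrogateSpec("raster_marginal", seed=1))
        assert np.array_equal(shuf.matrix.sum(1), mat.sum(1))
        assert np.array_equal(shuf.matrix[:4].sum(0), mat[:4].sum(0))
        assert np.array_equal(shuf.matrix[4:].sum(0), mat[4:].sum(0))

    def test_single_unit_group_unchanged_with_warning(self):
        raster = BinnedRaster(np.array([[1, 0, 1]], np.uint8), 20)
        with pytest.warns(UserWarning, match="single unit"):
            shuf = raster_marginal_shuffle(raster, None, SurrogateSpec("raster_marginal"))
        assert np.array_equal(shuf.matrix, raster.matrix)

    def test_swaps_stay_within_layer_group(self, rng):
        # one group frozen (single unit), the other shuffled: frozen row intact
        mat = (rng.random((5, 60)) < 0.4).astype(np.uint8)
        raster = BinnedRaster(mat, 20)
        groups = {raster.unit_ids[0]: "L2_4"}
        groups.update({u: "L5_6" for u in raster.unit_ids[1:]})
        with pytest.warns(UserWarning):
            shuf = raster_marginal_shuffle(raster, groups,
                                           SurrogateSpec("raster_marginal", seed=2))
        assert np.array_equal(shuf.matrix[0], mat[0])
        assert np.array_equal(shuf.matrix[1:].sum(0), mat[1:].sum(0))

    def test_counts_above_one_rejected(self):
        raster = BinnedRaster(np.array([[2, 0], [0, 1]]), 20)
        with pytest.raises(ValueError, match="binarized"):
            raster_marginal_shuffle(raster, None, SurrogateSpec("raster_marginal"))

    def test_tiny_matrix_reaches_all_marginal_equivalents(self):
        """Checkerboard swaps cover the whole fiber of a 3x4 toy matrix."""
        mat = np.array(
            [[1, 1, 0, 0],
             [0, 1, 1, 0],
             [1, 0, 0, 1]], np.uint8)
        rows, cols = mat.sum(1), mat.sum(0)
        fiber = set()
        for bits in itertools.product([0, 1], repeat=12):
            cand = np.array(bits, np.uint8).reshape(3, 4)
            if np.array_equal(cand.sum(1), rows) and np.array_equal(cand.sum(0), cols):
                fiber.add(cand.tobytes())
        seen = set()
        raster = BinnedRaster(mat, 20)
        for s in range(300):
            shuf = raster_marginal_shuffle(raster, None,
                                           SurrogateSpec("raster_marginal", seed=s))
            seen.add(shuf.matrix.astype(np.uint8).tobytes())
        assert seen == fiber
        assert len(fiber) > 1

    def test_deterministic_given_seed(self, rng):
        mat = (rng.random((6, 50)) < 0.3).astype(np.uint8)
        raster = BinnedRaster(mat, 20)
        a = raster_marginal_shuffle(raster, None, SurrogateSpec("raster_marginal", seed=9))
        b = raster_marginal_shuffle(raster, None, SurrogateSpec("raster_marginal", seed=9))
        assert np.array_equal(a.matrix, b.matrix)


class TestEnsemble:
    def test_constant_statistic_zero_width_interval(self, toy_units, toy_periods):
        inside = [
            u.with_times(u.spike_times[toy_periods.contains(u.spike_times)])
            for u in toy_units
        ]
        res = surrogate_ensemble(
            inside, SurrogateSpec("jitter", n_repeats=10, seed=3),
            statistic=lambda draw: 7.5, periods=toy_periods,
        )
        assert res.lo == res.hi == res.mean == 7.5

    def test_repeat_count_honored(self, toy_units, toy_periods):
        inside = [
            u.with_times(u.spike_times[toy_periods.contains(u.spike_times)])
            for u in toy_units
        ]
        res = surrogate_ensemble(
            inside, SurrogateSpec("jitter", n_repeats=100, seed=3),
            statistic=lambda draw: sum(u.n_spikes for u in draw),
            periods=toy_periods,
        )
        assert res.n_repeats == 100
        # jitter conserves counts, so the statistic is constant across draws
        assert np.ptp(res.values) == 0

    def test_ensemble_reproducible_from_seed(self, rng):
        mat = (rng.random((5, 40)) < 0.3).astype(np.uint8)
        raster = BinnedRaster(mat, 20)
        spec = SurrogateSpec("raster_marginal", n_repeats=8, seed=17)
        stat = lambda r: float((r.matrix[0] & r.matrix[1]).sum())
        a = surrogate_ensemble(raster, spec, stat)
        b = surrogate_ensemble(raster, spec, stat)
        assert np.array_equal(a.values, b.values)
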