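"""Difference-of-Gaussians kernel and pairwise spike-rate correlations."""

import numpy as np
import pytest

from burstsync.correlations import (
    build_kernel,
    convolved_traces,
    n_limited_mean,
    pairwise_correlations,
    window_sweep,
)
from burstsync.raster import SpikeTrain, bin_spikes
from burstsync.segmentation import ActivePeriodSet
from burstsync.synthetic import SyntheticConfig, generate_raster


class TestKernel:
    @pytest.mark.parametrize("rapid,mult", [(20, 4), (5, 4), (100, 2.5)])
    def test_zero_dc_and_symmetry(self, rapid, mult):
        k = build_kernel(rapid, mult)
        assert abs(k.sum()) < 1e-12
        assert np.allclose(k, k[::-1])
        assert k[k.size // 2] > 0  # positive rapid lobe at center

    def test_annihilates_constant_rate(self):
        k = build_kernel(20, 4)
        out = np.convolve(np.ones(5_000), k, mode="same")
        interior = out[k.size : -k.size]
        assert np.abs(interior).max() < 1e-10

    def test_single_spike_gives_closed_form_dog(self):
        sd_f, mult = 20.0, 4.0
        k = build_kernel(sd_f, mult)
        u = SpikeTrain("u", np.array([2_000]), "L2_4", "single", 4_000)
        trace = convolved_traces([u], k, dtype=np.float64)[0]
        t = np.arange(4_000) - 2_000.0
        sd_s = mult * sd_f
        expected = (
            np.exp(-0.5 * (t / sd_f) ** 2) / (np.sqrt(2 * np.pi) * sd_f)
            - np.exp(-0.5 * (t / sd_s) ** 2) / (np.sqrt(2 * np.pi) * sd_s)
        )
        # closed form vs truncated discrete kernel: matches to truncation error
        assert np.abs(trace - expected).max() < 1e-4

    def test_fwhm_mode_rescales_sd(self):
        k_sd = build_kernel(20 / (2 * np.sqrt(2 * np.log(2))), 4, "sd")
        k_fwhm = build_kernel(20, 4, "fwhm")
        assert np.allclose(k_sd, k_fwhm)


class TestPairwise:
    def test_duplicated_train_perfectly_correlated(self, rng):
        t = np.unique(rng.integers(0, 60_000, size=400))
        units = [
            SpikeTrain(n, t, "L2_4", "single", 60_000) for n in ("a", "b")
        ]
        res = pairwise_correlations(units)
        assert res.matrix[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_independent_poisson_near_zero(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 600_000, size=3_000)),
                       "L2_4", "single", 600_000)
            for i in range(4)
        ]
        res = pairwise_correlations(units)
        assert np.abs(res.pair_values()).max() < 0.02

    def test_planted_correlation_matches_binned_count_oracle(self):
        cfg = SyntheticConfig(regime="juvenile", n_units=4, n_mua=0,
                              duration_ms=600_000, in_burst_rate_hz=5.0,
                              shared_fast_corr=0.3, seed=41)
        units, _ = generate_raster(cfg)
        est = pairwise_correlations(units).mean_correlation
        counts = bin_spikes(units, 20).matrix
        oracle = np.corrcoef(counts)[np.triu_indices(4, k=1)].mean()
        assert est == pytest.approx(oracle, abs=0.05)

    def test_zero_variance_unit_gives_nan_pairs(self, rng):
        t = np.unique(rng.integers(0, 10_000, size=100))
        units = [
            SpikeTrain("a", t, "L2_4", "single", 10_000),
            SpikeTrain("b", np.array([], np.int64), "L2_4", "single", 10_000),
        ]
        res = pairwise_correlations(units)
        assert np.isnan(res.matrix[0, 1])

    def test_matrix_symmetric_unit_diagonal(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 60_000, size=300)),
                       "L2_4", "single", 60_000)
            for i in range(5)
        ]
        res = pairwise_correlations(units)
        assert np.allclose(res.matrix, res.matrix.T, equal_nan=True)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_layer_subgroup_filtering(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 30_000, size=150)),
                       "L2_4" if i < 3 else "L5_6", "single", 30_000)
            for i in range(6)
        ]
        res = pairwise_correlations(units, layer_group="L5_6")
        assert res.unit_ids == ["u3", "u4", "u5"]

    def test_active_only_restriction_changes_sample_set(self):
        cfg = SyntheticConfig(regime="neonatal", n_units=6, n_mua=2,
                              duration_ms=600_000, slow_mod_var=0.4,
                              slow_block_ms=500, seed=42)
        units, truth = generate_raster(cfg)
        k = build_kernel(400, 4)
        total = pairwise_correlations(units, k).mean_correlation
        active = pairwise_correlations(units, k, truth.schedule,
                                       "active_only").mean_correlation
        # down-states plus slow gain comodulate everything at slow scales;
        # restricting to active time must remove the down-state component
        assert total > active


class TestSweepAndSubsets:
    def test_white_noise_flat_near_zero(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 1_200_000, size=6_000)),
                       "L2_4", "single", 1_200_000)
            for i in range(4)
        ]
        sweep = window_sweep(units, None, [20, 100, 400], "total")
        # largest window has ~750 effective samples -> pair noise ~0.04/sqrt(6)
        assert np.abs(sweep.mean_r).max() < 0.04

    def test_fixed_slow_variant_requires_wider_slow(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 30_000, size=200)),
                       "L2_4", "single", 30_000)
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="slow"):
            window_sweep(units, None, [100], "total", fixed_slow_sd=80)

    def test_n_limited_equals_full_mean_when_n_matches(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 60_000, size=400)),
                       "L2_4", "single", 60_000)
            for i in range(6)
        ]
        k = build_kernel()
        full = pairwise_correlations(units, k).mean_correlation
        limited = n_limited_mean(units, k, n=6, repeats=5, rng=rng)
        assert limited == pytest.approx(full, abs=1e-12)

    def test_subset_means_concentrate_on_population_mean(self, rng):
        units = [
            SpikeTrain(f"u{i}", np.unique(rng.integers(0, 120_000, size=700)),
                       "L2_4", "single", 120_000)
            for i in range(16)
        ]
        k = build_kernel()
        full = pairwise_correlations(units, k).mean_correlation
        limited = n_limited_mean(units, k, n=12, repeats=20, rng=rng)
        assert limited == pytest.approx(full, abs=0.01)
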