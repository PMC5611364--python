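"""Data model, readers, binning and ISI-violation QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstsync.raster import (
    SpikeTrain,
    bin_spikes,
    load_phy,
    load_spike_table,
    qc_refractory_fraction,
    round_to_ms,
    total_mua,
    write_spike_table,
)


class TestRounding:
    @pytest.mark.parametrize(
        "raw,expected",
        [(1000.6, 1001), (1000.4, 1000), (1000.5, 1001), (0.5, 1), (2.5, 3), (0.49, 0)],
    )
    def test_nearest_ms_half_away_from_zero(self, raw, expected):
        assert round_to_ms(np.array([raw]))[0] == expected


class TestSpikeTable:
    def test_round_trip_exact(self, toy_units, tmp_path):
        path = tmp_path / "spikes.tsv"
        write_spike_table(path, toy_units)
        back = {u.unit_id: u for u in load_spike_table(path)}
        assert set(back) == {u.unit_id for u in toy_units}
        for u in toy_units:
            b = back[u.unit_id]
            assert np.array_equal(b.spike_times, u.spike_times)
            assert (b.layer_group, b.unit_class, b.recording_duration) == (
                u.layer_group, u.unit_class, u.recording_duration,
            )

    def test_fractional_times_rounded(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "#duration_ms=2000\nunit_id\ttime_ms\tlayer_group\tunit_class\n"
            "u1\t1000.6\tL2_4\tsingle\n"
        )
        (unit,) = load_spike_table(path)
        assert unit.spike_times.tolist() == [1001]

    def test_empty_table(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("unit_id\ttime_ms\tlayer_group\tunit_class\n")
        assert load_spike_table(path) == []

    def test_unknown_layer_label_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "unit_id\ttime_ms\tlayer_group\tunit_class\nu1\t5\tL9\tsingle\n"
        )
        with pytest.raises(ValueError, match=":2"):
            load_spike_table(path)

    def test_unparseable_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "unit_id\ttime_ms\tlayer_group\tunit_class\nu1\txx\tL2_4\tsingle\n"
        )
        with pytest.raises(ValueError, match=":2"):
            load_spike_table(path)


class TestPhyReader:
    def test_matches_spike_table_contents(self, tmp_path):
        rate = 32_000.0
        samples = np.array([320, 32_000, 64_016, 96_000])  # 10, 1000, 2000.5, 3000 ms
        clusters = np.array([3, 7, 3, 9])
        np.save(tmp_path / "spike_times.npy", samples)
        np.save(tmp_path / "spike_clusters.npy", clusters)
        (tmp_path / "params.py").write_text("sample_rate = 32000.\n")
        (tmp_path / "cluster_group.tsv").write_text(
            "cluster_id\tgroup\n3\tgood\n7\tmua\n9\tnoise\n"
        )
        (tmp_path / "cluster_layers.tsv").write_text(
            "cluster_id\tlayer_group\n3\tL2_4\n7\tL5_6\n9\tL5_6\n"
        )
        units = {u.unit_id: u for u in load_phy(tmp_path, duration_ms=5_000)}
        assert set(units) == {"3", "7"}  # noise cluster dropped
        assert units["3"].spike_times.tolist() == [10, 2001]  # 2000.5 rounds up
        assert units["3"].unit_class == "single"
        assert units["7"].unit_class == "multi"

    def test_missing_layer_assignment_raises(self, tmp_path):
        np.save(tmp_path / "spike_times.npy", np.array([320]))
        np.save(tmp_path / "spike_clusters.npy", np.array([3]))
        (tmp_path / "params.py").write_text("sample_rate = 32000\n")
        (tmp_path / "cluster_group.tsv").write_text("cluster_id\tgroup\n3\tgood\n")
        (tmp_path / "cluster_layers.tsv").write_text("cluster_id\tlayer_group\n")
        with pytest.raises(ValueError, match="layer_group"):
            load_phy(tmp_path)


class TestBinning:
    def test_spike_lands_in_expected_bin(self):
        u = SpikeTrain("u", np.array([25]), "L2_4", "single", 100)
        raster = bin_spikes([u], 20)
        assert raster.matrix[0].tolist() == [0, 1, 0, 0, 0]

    def test_binarize_collapses_multi_spike_bins(self):
        u = SpikeTrain("u", np.array([3, 3, 4]), "L2_4", "single", 10)
        assert bin_spikes([u], 1, binarize=True).matrix[0].tolist() == [0, 0, 0, 1, 1] + [0] * 5

    def test_column_sums_match_histogram_oracle(self, rng):
        t = np.sort(rng.integers(0, 10_000, size=10_000))
        u = SpikeTrain("u", t, "L2_4", "single", 10_000)
        raster = bin_spikes([u], 7)
        hi = raster.n_bins * 7
        expected = np.bincount(t[t < hi] // 7, minlength=raster.n_bins)
        assert np.array_equal(raster.matrix[0], expected)

    def test_1ms_binning_conserves_total_count(self, toy_units):
        raster = bin_spikes(toy_units, 1)
        assert raster.matrix.sum() == sum(u.n_spikes for u in toy_units)

    def test_partial_trailing_bin_dropped(self):
        u = SpikeTrain("u", np.array([95]), "L2_4", "single", 99)
        assert bin_spikes([u], 20).n_bins == 4

    def test_total_mua_sums_all_clusters(self, toy_units):
        tmua = total_mua(toy_units)
        assert tmua.matrix.sum() == sum(u.n_spikes for u in toy_units)
        assert tmua.n_units == 1


class TestRefractoryQC:
    def test_forced_fraction(self):
        u = SpikeTrain("u", np.array([0, 1, 10]), "L2_4", "single", 100)
        assert qc_refractory_fraction(u) == 0.5

    def test_regular_train_clean(self):
        u = SpikeTrain("u", np.arange(0, 10_000, 100), "L2_4", "single", 10_000)
        assert qc_refractory_fraction(u) == 0.0

    def test_too_few_spikes_undefined(self):
        u = SpikeTrain("u", np.array([5]), "L2_4", "single", 100)
        assert np.isnan(qc_refractory_fraction(u))

    def test_poisson_rate_matches_exponential_law_and_direct_count(self, rng):
        # Poisson train with rate r and violation window v: expected fraction
        # P(ISI < v) = 1 - exp(-r v). A 20 ms window keeps 1 ms rounding
        # negligible relative to the threshold.
        isis = rng.exponential(2_000.0, size=9_000)  # 0.5 Hz
        t = round_to_ms(np.cumsum(isis))
        u = SpikeTrain("u", t, "L2_4", "single", int(t[-1]) + 1)
        frac = qc_refractory_fraction(u, violation_ms=20)
        direct = np.mean(np.diff(t) < 20)
        assert frac == direct
        assert frac == pytest.approx(1 - np.exp(-0.01), abs=0.003)

    def test_invariant_to_time_shift(self, toy_units):
        u = toy_units[0]
        shifted = SpikeTrain("s", u.spike_times + 500, u.layer_group,
                             u.unit_class, u.recording_duration + 500)
        assert qc_refractory_fraction(u) == qc_refractory_fraction(shifted)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=4_999), min_size=0, max_size=200),
    st.integers(min_value=1, max_value=50),
)
def test_binning_count_conservation_property(times, width):
    """Property: without binarization, bin counts sum to the in-range spikes."""
    u = SpikeTrain("u", np.sort(np.array(times, np.int64)), "L2_4", "single", 5_000)
    raster = bin_spikes([u], width)
    in_range = np.sum(np.array(times) < raster.n_bins * width)
    assert raster.matrix.sum() == in_range
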