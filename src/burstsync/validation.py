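"""Validation studies: the canonical synthetic benchmarks for every stage.

Each function sets up one ground-truthed study condition with the synthetic
generator, runs the corresponding analysis stage, and returns a flat dict of
measured quantities. The conditions (sample sizes, rates, surrogate repeat
counts) are fixed here so the test suite and the reproduction script measure
the same thing.

The ``_naive_*`` helpers are deliberately simple reference implementations
(plain loops over windows, bins and spikes) used as independent oracles for
the vectorized code paths; they must stay naive.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.stats import spearmanr

from .correlations import (
    build_kernel,
    convolved_traces,
    jitter_band,
    pairwise_correlations,
    window_sweep,
)
from .coupling import normalized_coupling, stpr_curves
from .events import deviation_index, event_size_distribution, window_spike_counts
from .raster import BinnedRaster, SpikeTrain, bin_spikes, single_units, total_mua
from .segmentation import ActivePeriodSet, detect_active_periods, fraction_active, rate_summary
from .surrogates import SurrogateSpec, child_rngs, jitter_spikes, raster_marginal_shuffle
from .synthetic import SyntheticConfig, generate_raster, regime_presets
from .words import extract_words

__all__ = [
    "marginal_exactness",
    "jitter_conservation",
    "null_self_consistency",
    "oracle_equivalence",
    "segmentation_recovery",
    "correlation_recovery",
    "slow_dissociation",
    "coupling_recovery",
    "rate_invariance",
]


def _child_seed(seed: int, k: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Surrogate exactness
# ---------------------------------------------------------------------------


def marginal_exactness(seed: int = 0, n_matrices: int = 1000) -> dict:
    """Row-sum / within-group column-sum conservation on random binary matrices."""
    import warnings

    rng = np.random.default_rng(_child_seed(seed, 0))
    row_violations = col_violations = n_changed = 0
    for _ in range(n_matrices):
        n_units = int(rng.integers(3, 13))
        n_bins = int(rng.integers(10, 61))
        mat = (rng.random((n_units, n_bins)) < rng.uniform(0.05, 0.5)).astype(np.uint8)
        raster = BinnedRaster(mat, 20)
        groups = {
            uid: ("L2_4" if i < n_units // 2 else "L5_6")
            for i, uid in enumerate(raster.unit_ids)
        }
        spec = SurrogateSpec("raster_marginal", seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            # a random split can leave one-unit groups; they stay unshuffled
            warnings.simplefilter("ignore", UserWarning)
            shuf = raster_marginal_shuffle(raster, groups, spec)
        if not np.array_equal(shuf.matrix.sum(1), mat.sum(1)):
            row_violations += 1
        for g in ("L2_4", "L5_6"):
            rows = [i for i, u in enumerate(raster.unit_ids) if groups[u] == g]
            if not np.array_equal(shuf.matrix[rows].sum(0), mat[rows].sum(0)):
                col_violations += 1
        if not np.array_equal(shuf.matrix, mat):
            n_changed += 1
    return dict(
        n_matrices=n_matrices,
        row_sum_violations=row_violations,
        group_col_sum_violations=col_violations,
        n_changed=n_changed,
    )


def jitter_conservation(seed: int = 0, n_rasters: int = 100) -> dict:
    """Per-unit count conservation and in-active support on random rasters."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    count_violations = support_violations = 0
    for _ in range(n_rasters):
        duration = 60_000
        cfg = SyntheticConfig(
            regime="neonatal",
            n_units=int(rng.integers(2, 8)),
            n_mua=0,
            duration_ms=duration,
            active_duration_range=(1_000, 5_000),
            inter_event_range=(2_000, 8_000),
            in_burst_rate_hz=float(rng.uniform(2, 10)),
            seed=int(rng.integers(2**31)),
        )
        units, truth = generate_raster(cfg)
        spec = SurrogateSpec("jitter", seed=int(rng.integers(2**31)))
        jit = jitter_spikes(units, truth.schedule, spec)
        for u, j in zip(units, jit):
            if u.n_spikes != j.n_spikes:
                count_violations += 1
            if not truth.schedule.contains(j.spike_times).all():
                support_violations += 1
    return dict(
        n_rasters=n_rasters,
        count_violations=count_violations,
        support_violations=support_violations,
    )


# ---------------------------------------------------------------------------
# Null self-consistency (Poisson-within-active data)
# ---------------------------------------------------------------------------


def _poisson_neonatal(seed: int, n_units: int = 12) -> tuple[list[SpikeTrain], ActivePeriodSet]:
    """Exactly-Poisson firing on the neonatal schedule (no modulation)."""
    cfg = regime_presets(
        "P6_7",
        seed=seed,
        n_units=n_units,
        n_mua=4,
        oscillation_depth=0.0,
        slow_mod_var=0.0,
        shared_fast_corr=0.0,
    )
    units, truth = generate_raster(cfg)
    return units, truth.schedule


def null_self_consistency(
    seed: int = 0,
    window_ms: int = 20,
    n_jitter: int = 50,
    n_marginal: int = 20,
    well_sampled_windows: float = 1e4,
) -> dict:
    """Deviation indices on exactly-Poisson data, where they should be ~0.

    Event sizes: observed vs the mean of ``n_jitter`` wrap-jitter draws.
    Sizes are reported with their observed window counts; the headline
    figure is the largest |index| among well-sampled sizes (>=
    ``well_sampled_windows`` observed windows — rarer sizes carry
    Monte-Carlo noise far above any fixed tolerance).

    Words: the observed mean occurrence index against the average of
    ``n_marginal`` raster-marginal surrogates, with a leave-one-out null
    distribution (each surrogate scored against the mean of the others)
    giving the Monte-Carlo 95% interval around 0.
    """
    units, periods = _poisson_neonatal(_child_seed(seed, 2))
    sus = single_units(units)

    obs = event_size_distribution(sus, periods, window_ms)
    jp: dict[int, list[float]] = {}
    spec = SurrogateSpec("jitter", seed=_child_seed(seed, 3))
    for rng in child_rngs(spec.seed, n_jitter):
        jit = jitter_spikes(sus, periods, spec, rng=rng)
        d = event_size_distribution(jit, periods, window_ms)
        for k, p in d.probabilities.items():
            jp.setdefault(k, []).append(p)
    jitter_mean = {k: float(np.mean(v)) for k, v in jp.items()}
    dev = deviation_index(obs.probabilities, jitter_mean)
    event_table = {
        k: dict(
            observed_windows=obs.probabilities.get(k, 0.0) * obs.n_windows_total,
            index=float(dev.get(k, np.nan)),
        )
        for k in sorted(dev.index)
    }
    well = [
        abs(row["index"])
        for row in event_table.values()
        if row["observed_windows"] >= well_sampled_windows and np.isfinite(row["index"])
    ]
    max_index_well_sampled = float(max(well)) if well else float("nan")

    # word self-consistency against the raster-marginal null
    raster = bin_spikes(units, 20, binarize=True)
    layer_map = {u.unit_id: u.layer_group for u in units}
    su_ids = {u.unit_id for u in sus}
    su_rows = [i for i, uid in enumerate(raster.unit_ids) if uid in su_ids]
    mspec = SurrogateSpec("raster_marginal", seed=_child_seed(seed, 4))

    def words_of(r: BinnedRaster) -> Counter:
        sub = BinnedRaster(r.matrix[su_rows], 20, [r.unit_ids[i] for i in su_rows])
        w, _ = extract_words(sub, periods)
        return w

    obs_words = words_of(raster)
    # n_marginal + 1 surrogates so that the observed raster and every null
    # candidate are each scored against exactly n_marginal non-self draws
    # (the mean index against an averaged null carries a type-richness bias
    # that only cancels when the comparison is symmetric)
    surr = [
        words_of(raster_marginal_shuffle(raster, layer_map, mspec, rng=rng))
        for rng in child_rngs(mspec.seed, n_marginal + 1)
    ]

    def mean_index(target: Counter, others: list[Counter]) -> float:
        avg: Counter = Counter()
        for o in others:
            avg.update(o)
        n = len(others)
        keys = set(target) | set(avg)
        vals = []
        for w in keys:
            a, b = target.get(w, 0), avg.get(w, 0) / n
            if a + b > 0:
                vals.append((a - b) / (a + b))
        return float(np.mean(vals)) if vals else float("nan")

    word_mean_index = mean_index(obs_words, surr[1:])
    loo = [
        mean_index(surr[i], surr[:i] + surr[i + 1 :]) for i in range(len(surr))
    ]
    return dict(
        event_table=event_table,
        max_index_well_sampled=max_index_well_sampled,
        word_mean_index=word_mean_index,
        word_null_mean=float(np.mean(loo)),
        word_null_lo=float(np.percentile(loo, 2.5)),
        word_null_hi=float(np.percentile(loo, 97.5)),
        word_mean_index_single_draw=mean_index(obs_words, surr[:1]),
    )


# ---------------------------------------------------------------------------
# Oracle equivalence on toy rasters
# ---------------------------------------------------------------------------


def _naive_window_counts(units, periods, window_ms, step_ms):
    out = []
    for s, e in periods.intervals:
        start = s
        while start + window_ms <= e:
            out.append(
                [
                    int(np.sum((u.spike_times >= start) & (u.spike_times < start + window_ms)))
                    for u in units
                ]
            )
            start += step_ms
    return np.array(out, dtype=int).T if out else np.zeros((len(units), 0), int)


def _naive_words(units, periods, bin_ms=20, min_size=3):
    words: Counter = Counter()
    n_bins = 0
    duration = max(u.recording_duration for u in units)
    for b in range(0, duration - bin_ms + 1, bin_ms):
        inside = any(s <= b and b + bin_ms <= e for s, e in periods.intervals)
        if not inside:
            continue
        n_bins += 1
        active = frozenset(
            u.unit_id
            for u in units
            if np.any((u.spike_times >= b) & (u.spike_times < b + bin_ms))
        )
        if len(active) >= min_size:
            words[active] += 1
    return words, n_bins


def _gaussian_weights(sd: float, truncate: float = 4.0) -> np.ndarray:
    r = int(truncate * sd + 0.5)
    t = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-0.5 * (t / sd) ** 2)
    return w / w.sum()


def _naive_stpr(units, trigger_idx, lag_ms, smooth_sd):
    mats = [np.asarray(bin_spikes([u], 1, binarize=True).matrix[0], float) for u in units]
    T = max(m.size for m in mats)
    mats = [np.pad(m, (0, T - m.size)) for m in mats]
    g = _gaussian_weights(smooth_sd)
    curves = []
    for i in trigger_idx:
        pop = np.zeros(T)
        for j, m in enumerate(mats):
            if j != i:
                pop += m
        trace = np.convolve(pop, g, mode="same")
        spikes = np.flatnonzero(mats[i])
        spikes = spikes[(spikes >= lag_ms) & (spikes < T - lag_ms)]
        segs = [trace[s - lag_ms : s + lag_ms + 1] for s in spikes]
        curves.append(np.mean(segs, axis=0) if segs else np.full(2 * lag_ms + 1, np.nan))
    return np.array(curves)


def oracle_equivalence(seed: int = 0) -> dict:
    """Vectorized stages vs naive loop oracles on a toy raster (6 units, 20 s)."""
    rng = np.random.default_rng(_child_seed(seed, 5))
    duration = 20_000
    periods = ActivePeriodSet(
        np.array([[500, 6_000], [9_000, 14_500], [16_000, 19_980]]), duration
    )
    units = []
    for i in range(6):
        n = int(rng.integers(150, 400))
        t = np.unique(rng.integers(0, duration, size=n))
        units.append(SpikeTrain(f"u{i}", t, "L2_4" if i < 3 else "L5_6", "single", duration))

    counts = window_spike_counts(units, periods, 20, 1)
    naive_counts = _naive_window_counts(units, periods, 20, 1)
    event_diff = int(np.abs(counts - naive_counts).max()) if counts.size else 0

    words, n_bins = extract_words(units, periods)
    naive_w, naive_bins = _naive_words(units, periods)
    word_diff = 0 if (words == naive_w and n_bins == naive_bins) else 1

    kernel = build_kernel(20, 4)
    traces = convolved_traces(units, kernel, dtype=np.float64)
    naive_traces = np.array(
        [
            np.convolve(np.asarray(bin_spikes([u], 1).matrix[0], float), kernel, mode="same")
            for u in units
        ]
    )
    m = min(traces.shape[1], naive_traces.shape[1])
    conv_diff = float(np.abs(traces[:, :m] - naive_traces[:, :m]).max())

    raster = bin_spikes(units, 1, binarize=True)
    curves = stpr_curves(raster, [0, 3], lag_ms=200, smooth_sd=10.0)
    naive_curves = _naive_stpr(units, [0, 3], 200, 10.0)
    stpr_diff = float(np.nanmax(np.abs(curves - naive_curves)))

    return dict(
        event_count_max_diff=event_diff,
        word_table_mismatch=word_diff,
        convolution_max_diff=conv_diff,
        stpr_max_diff=stpr_diff,
    )


# ---------------------------------------------------------------------------
# Segmentation, correlations, coupling, rates
# ---------------------------------------------------------------------------


def segmentation_recovery(seed: int = 0, duration_ms: int = 1_800_000) -> dict:
    """Detected vs planted active periods on the neonatal preset."""
    cfg = regime_presets("P6_7", seed=_child_seed(seed, 6), duration_ms=duration_ms)
    units, truth = generate_raster(cfg)
    detected = detect_active_periods(total_mua(units))
    true_mask = truth.schedule.mask()
    det_mask = detected.mask()
    jaccard = float((true_mask & det_mask).sum() / (true_mask | det_mask).sum())
    return dict(
        jaccard=jaccard,
        fraction_active=fraction_active(detected),
        analytic_duty_cycle=cfg.duty_cycle,
        realized_duty_cycle=fraction_active(truth.schedule),
    )


def correlation_recovery(
    seed: int = 0,
    rhos: tuple[float, ...] = (0.0, 0.1, 0.3),
    duration_ms: int = 1_800_000,
    n_band_repeats: int = 100,
) -> dict:
    """Planted fast correlation vs the kernel estimate, and band coverage.

    For each target rho, six fully coupled units (30 min, continuous) are
    generated; reported are the mean kernel correlation and the mean binned
    20 ms count correlation (the direct oracle on the same realization).
    Band coverage: an independent-unit neonatal raster is scored against its
    own 100-repeat jitter band (fraction of histogram bins covered).
    """
    kernel = build_kernel(20, 4)
    estimates, oracles = {}, {}
    for j, rho in enumerate(rhos):
        cfg = SyntheticConfig(
            regime="juvenile",
            n_units=6,
            n_mua=0,
            duration_ms=duration_ms,
            in_burst_rate_hz=5.0,
            shared_fast_corr=rho,
            seed=_child_seed(seed, 10 + j),
        )
        units, _ = generate_raster(cfg)
        estimates[rho] = pairwise_correlations(units, kernel).mean_correlation
        binned = bin_spikes(units, 20).matrix
        cc = np.corrcoef(binned)
        oracles[rho] = float(cc[np.triu_indices(len(units), k=1)].mean())

    cfg = SyntheticConfig(
        regime="neonatal",
        n_units=12,
        n_mua=4,
        duration_ms=duration_ms,
        in_burst_rate_hz=5.0,
        seed=_child_seed(seed, 20),
    )
    units, truth = generate_raster(cfg)
    band = jitter_band(
        units, truth.schedule, kernel,
        SurrogateSpec("jitter", n_repeats=n_band_repeats, seed=_child_seed(seed, 21)),
    )
    res = pairwise_correlations(units, kernel)
    h, _ = np.histogram(res.pair_values(), bins=band["edges"])
    h = h / max(res.pair_values().size, 1)
    coverage = float(((h >= band["lo"]) & (h <= band["hi"])).mean())
    return dict(
        kernel_estimates=estimates,
        count_oracles=oracles,
        band_coverage=coverage,
        mean_corr_independent=res.mean_correlation,
    )


def slow_dissociation(seed: int = 0, duration_ms: int = 1_800_000) -> dict:
    """Slow shared modulation only: rising total-restriction sweep, flat active-only."""
    cfg = regime_presets(
        "P6_7",
        seed=_child_seed(seed, 30),
        n_units=12,
        n_mua=4,
        duration_ms=duration_ms,
        oscillation_depth=0.0,
        shared_fast_corr=0.0,
        slow_mod_var=0.25,
        coupling_weights=np.ones(12),  # planted condition: full-weight slow gain
    )
    units, truth = generate_raster(cfg)
    sweep = window_sweep(units, truth.schedule, [20, 100, 400], "total")
    active20 = window_sweep(units, truth.schedule, [20], "active_only")
    return dict(
        total_by_window={int(r.rapid_sd_ms): float(r.mean_r) for r in sweep.itertuples()},
        active_only_20ms=float(active20.mean_r.iloc[0]),
    )


def coupling_recovery(seed: int = 0, duration_ms: int = 1_800_000) -> dict:
    """Planted coupling-weight ranking, and self-normalization of the marginal null.

    24 single units (continuous regime, one layer group so a single
    normalization constant applies) carry evenly spaced coupling weights in
    [0, 1]; reported is the Spearman correlation between planted weights and
    recovered normalized couplings. For the self-normalization check, a
    marginal-shuffled raster is fed back as "observed": its mean coupling
    should be ~1 by construction.
    """
    w = np.linspace(0, 1, 24)
    cfg = SyntheticConfig(
        regime="juvenile",
        n_units=24,
        n_mua=4,
        duration_ms=duration_ms,
        in_burst_rate_hz=5.0,
        shared_fast_corr=0.3,
        slow_mod_var=0.1,
        coupling_weights=w,
        frac_superficial=1.0,
        seed=_child_seed(seed, 40),
    )
    units, truth = generate_raster(cfg)
    res = normalized_coupling(
        units, "L2_4",
        SurrogateSpec("raster_marginal", seed=_child_seed(seed, 41)),
        n_surrogates=10,
    )
    order = {u.unit_id: wi for u, wi in zip(units, w)}
    planted = [order[uid] for uid in res.unit_ids]
    rho = float(spearmanr(planted, res.coupling).statistic)

    # marginal-shuffled raster fed back as observed data
    small = SyntheticConfig(
        regime="juvenile",
        n_units=12,
        n_mua=2,
        duration_ms=600_000,
        in_burst_rate_hz=5.0,
        shared_fast_corr=0.2,
        frac_superficial=1.0,
        seed=_child_seed(seed, 42),
    )
    sunits, _ = generate_raster(small)
    raster = bin_spikes(sunits, 1, binarize=True)
    shuf = raster_marginal_shuffle(
        raster, None, SurrogateSpec("raster_marginal", seed=_child_seed(seed, 43))
    )
    shuffled_units = [
        SpikeTrain(u.unit_id, np.flatnonzero(shuf.matrix[i]), u.layer_group,
                   u.unit_class, u.recording_duration)
        for i, u in enumerate(sunits)
    ]
    self_res = normalized_coupling(
        shuffled_units, "L2_4",
        SurrogateSpec("raster_marginal", seed=_child_seed(seed, 44)),
        n_surrogates=10,
    )
    return dict(
        spearman_weights=rho,
        mean_coupling=res.mean_coupling,
        shuffled_mean_coupling=self_res.mean_coupling,
    )


def rate_invariance(seed: int = 0, duration_ms: int = 1_800_000) -> dict:
    """Active-period rates equal across ages while total rates differ (presets)."""
    out = {}
    for j, age in enumerate(("P6_7", "P24")):
        cfg = regime_presets(age, seed=_child_seed(seed, 50 + j), duration_ms=duration_ms)
        units, _ = generate_raster(cfg)
        periods = detect_active_periods(total_mua(units))
        rs = rate_summary(units, periods).query("unit_class == 'single'")
        out[age] = dict(
            total_rate_hz=float(rs.total_rate_hz.mean()),
            active_rate_hz=float(rs.active_rate_hz.mean()),
        )
    out["active_rate_ratio"] = out["P6_7"]["active_rate_hz"] / out["P24"]["active_rate_hz"]
    out["total_rate_ratio"] = out["P24"]["total_rate_hz"] / out["P6_7"]["total_rate_hz"]
    return out
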