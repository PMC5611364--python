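"""Ground-truthed synthetic spike rasters with developmental activity structure.

The generator emulates the statistical features of spontaneous activity in
developing visual cortex that the analysis modules are built to measure:

* **Discontinuity** — in the neonatal regime, firing is restricted to active
  periods of 2-10 s separated by 30-60 s of network silence (retinal-wave
  driven events); the juvenile regime is continuously active.
* **Oscillation-locked firing** — within active periods, spike probability
  is modulated at a spindle-burst-like frequency (default 15 Hz; the
  frequency and depth are qualitative stand-ins, configurable).
* **Shared rate comodulation** — a common multiplicative gain with a fast
  (20 ms block) and a slow (1 s block) component. The fast component is
  calibrated in closed form so that the 20 ms-scale pairwise spike-count
  correlation of fully coupled units hits ``shared_fast_corr``.
* **Heterogeneous population coupling** — per-unit weights in [0, 1] scale
  each unit's sensitivity to the common gain.
* **Planted words** — specific unit sets can be made to co-fire within one
  20 ms bin at a scheduled rate.

Spikes are Bernoulli-thinned on a 1 ms grid (at most one spike per unit per
ms), so per-ms spike probability equals the instantaneous intensity and the
mean in-burst rate is exact by construction. Gain blocks are gamma
distributed (mean 1), which keeps intensities non-negative without clipping
and makes the count-correlation calibration exact:
``Var(gain) = rho / (mu * (1 - rho))`` with ``mu`` the expected in-burst
count per 20 ms bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .raster import SpikeTrain
from .segmentation import ActivePeriodSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_schedule",
    "generate_raster",
    "regime_presets",
    "fast_gain_variance",
    "AGE_GROUPS",
]

AGE_GROUPS = ("P6_7", "P8_9", "P10_11", "P15_17", "P24")

FAST_BLOCK_MS = 20
WORD_BIN_MS = 20


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic recording."""

    regime: str = "neonatal"  # {"neonatal", "juvenile"}
    n_units: int = 12  # good single units
    n_mua: int = 4  # multi-unit clusters (pooled neighbourhoods)
    duration_ms: int = 1_800_000  # 30 min
    active_duration_range: tuple[int, int] = (2_000, 10_000)
    inter_event_range: tuple[int, int] = (30_000, 60_000)
    in_burst_rate_hz: float = 5.0  # per single unit, within active periods
    mua_rate_multiplier: float = 5.0  # MUA clusters pool several neurons
    oscillation_freq_hz: float = 15.0
    oscillation_depth: float = 0.0  # [0, 1]
    shared_fast_corr: float = 0.0  # target 20 ms count correlation (w = 1 pairs)
    slow_mod_var: float = 0.0  # variance of the slow shared gain
    slow_block_ms: int = 1_000
    coupling_weights: Sequence[float] | None = None  # per single unit, [0, 1]
    frac_superficial: float = 0.5  # share of units assigned to L2_4
    planted_words: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("neonatal", "juvenile"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for lo, hi in (self.active_duration_range, self.inter_event_range):
            if lo < 0 or hi < lo:
                raise ValueError("invalid range")
        if self.in_burst_rate_hz < 0 or self.mua_rate_multiplier < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.oscillation_depth <= 1:
            raise ValueError("oscillation_depth must be in [0, 1]")
        if self.coupling_weights is not None:
            w = np.asarray(self.coupling_weights, float)
            if w.size != self.n_units or w.min() < 0 or w.max() > 1:
                raise ValueError("coupling_weights must be n_units values in [0, 1]")

    @property
    def duty_cycle(self) -> float:
        """Expected active fraction of the renewal schedule."""
        if self.regime == "juvenile":
            return 1.0
        d = np.mean(self.active_duration_range)
        g = np.mean(self.inter_event_range)
        return float(d / (d + g))

    def weights(self) -> np.ndarray:
        if self.coupling_weights is None:
            return np.ones(self.n_units)
        return np.asarray(self.coupling_weights, float)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["coupling_weights"] = (
            None if self.coupling_weights is None else list(map(float, self.coupling_weights))
        )
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class GroundTruth:
    """What the generator actually planted (the acceptance oracle)."""

    schedule: ActivePeriodSet
    duty_cycle: float
    in_burst_rate_hz: float
    coupling_weights: np.ndarray
    shared_fast_corr: float
    fast_gain_var: float
    planted_words: list[tuple[tuple[str, ...], float]]


def fast_gain_variance(rate_hz: float, rho: float, block_ms: int = FAST_BLOCK_MS) -> float:
    """Gain variance needed for a target count correlation at the block scale.

    For Bernoulli spiking at intensity ``rate * gain`` with block-constant
    gains of mean 1 and variance s2, the pairwise correlation of block
    counts between two fully coupled units is ``mu*s2 / (1 + mu*s2)`` with
    ``mu = rate * block``; inverting gives ``s2 = rho / (mu * (1 - rho))``.
    Raises for infeasible targets (rho outside [0, 1)), reporting the bound.
    """
    if rho == 0:
        return 0.0
    if not 0 <= rho < 1:
        raise ValueError(f"target correlation {rho} infeasible; attainable range is [0, 1)")
    mu = rate_hz * block_ms / 1000.0
    if mu <= 0:
        raise ValueError("target correlation > 0 infeasible at zero rate (bound 0)")
    return rho / (mu * (1.0 - rho))


def generate_schedule(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> ActivePeriodSet:
    """Draw the active/silent schedule (renewal process of uniform draws).

    The neonatal recording starts in silence; gaps and active durations are
    drawn uniformly from the configured ranges until the recording is
    filled, the last interval being truncated. The juvenile regime is one
    active period spanning the recording.
    """
    T = config.duration_ms
    if config.regime == "juvenile":
        return ActivePeriodSet(np.array([[0, T]]), T)
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
    intervals = []
    t = 0
    while t < T:
        g_lo, g_hi = config.inter_event_range
        t += int(rng.integers(g_lo, g_hi + 1)) if g_hi > 0 else 0
        if t >= T:
            break
        a_lo, a_hi = config.active_duration_range
        dur = int(rng.integers(a_lo, a_hi + 1))
        end = min(t + dur, T)
        if end > t:
            intervals.append((t, end))
        t = end
    iv = np.array(intervals, np.int64).reshape(-1, 2)
    return ActivePeriodSet(iv, T)


def _gamma_blocks(
    rng: np.random.Generator, n_blocks: int, var: float
) -> np.ndarray:
    """Mean-1 gamma multipliers, one per block (all-ones when var = 0)."""
    if var <= 0:
        return np.ones(n_blocks)
    shape = 1.0 / var
    return rng.gamma(shape, scale=var, size=n_blocks)


def generate_raster(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[SpikeTrain], GroundTruth]:
    """Generate the spike-train collection and its ground truth.

    Within active periods, unit ``i`` fires as an inhomogeneous Bernoulli
    process on the 1 ms grid with intensity::

        rate * (1 + depth * cos(2 pi f t)) * max(0, 1 + w_i * g(t))

    where ``g = (m_fast - 1) + (m_slow - 1)`` is the shared gain fluctuation
    (gamma blocks). MUA clusters use ``rate * mua_rate_multiplier`` and full
    weight. Planted words add one spike per member unit in a randomly chosen
    in-active 20 ms bin at the scheduled rate. No spikes occur outside
    active periods.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
    T = config.duration_ms
    schedule = generate_schedule(config, rng)
    act_idx = np.flatnonzero(schedule.mask())
    w = config.weights()
    s2_fast = fast_gain_variance(config.in_burst_rate_hz, config.shared_fast_corr)

    n_fast = T // FAST_BLOCK_MS + 1
    n_slow = T // config.slow_block_ms + 1
    m_fast = _gamma_blocks(rng, n_fast, s2_fast)
    m_slow = _gamma_blocks(rng, n_slow, config.slow_mod_var)
    if act_idx.size:
        g_act = (m_fast[act_idx // FAST_BLOCK_MS] - 1.0) + (
            m_slow[act_idx // config.slow_block_ms] - 1.0
        )
        osc = 1.0 + config.oscillation_depth * np.cos(
            2 * np.pi * config.oscillation_freq_hz * act_idx / 1000.0
        )
    else:
        g_act = osc = np.zeros(0)

    n_sup = int(round(config.frac_superficial * config.n_units))
    units: list[SpikeTrain] = []

    def _draw(rate_hz: float, weight: float) -> np.ndarray:
        p = (rate_hz / 1000.0) * osc * np.maximum(0.0, 1.0 + weight * g_act)
        hits = rng.random(act_idx.size) < np.minimum(p, 1.0)
        return act_idx[hits]

    for i in range(config.n_units):
        t = _draw(config.in_burst_rate_hz, w[i])
        layer = "L2_4" if i < n_sup else "L5_6"
        units.append(SpikeTrain(f"su{i:02d}", t, layer, "single", T))
    n_mua_sup = int(round(config.frac_superficial * config.n_mua))
    for j in range(config.n_mua):
        t = _draw(config.in_burst_rate_hz * config.mua_rate_multiplier, 1.0)
        layer = "L2_4" if j < n_mua_sup else "L5_6"
        units.append(SpikeTrain(f"mua{j:02d}", t, layer, "multi", T))

    planted: list[tuple[tuple[str, ...], float]] = []
    if config.planted_words:
        bins = _word_bins(schedule)
        active_s = schedule.total_active_ms / 1000.0
        for members, rate_hz in config.planted_words:
            ids = tuple(units[i].unit_id for i in members)
            n_events = rng.poisson(rate_hz * active_s)
            if bins.size and n_events:
                chosen = bins[rng.integers(0, bins.size, size=n_events)]
                for i in members:
                    extra = chosen + rng.integers(0, WORD_BIN_MS, size=n_events)
                    merged = np.unique(np.concatenate([units[i].spike_times, extra]))
                    units[i] = units[i].with_times(merged)
            planted.append((ids, rate_hz))

    truth = GroundTruth(
        schedule=schedule,
        duty_cycle=config.duty_cycle,
        in_burst_rate_hz=config.in_burst_rate_hz,
        coupling_weights=w.copy(),
        shared_fast_corr=config.shared_fast_corr,
        fast_gain_var=s2_fast,
        planted_words=planted,
    )
    return units, truth


def _word_bins(schedule: ActivePeriodSet) -> np.ndarray:
    """Start times of 20 ms bins lying fully inside active periods."""
    out = []
    for s, e in schedule.intervals:
        lo = int(np.ceil(s / WORD_BIN_MS)) * WORD_BIN_MS
        out.append(np.arange(lo, e - WORD_BIN_MS + 1, WORD_BIN_MS))
    return np.concatenate(out) if out else np.zeros(0, np.int64)


def regime_presets(age_group: str, **overrides) -> SyntheticConfig:
    """Age-group presets encoding the qualitative developmental trajectory.

    All presets share the same in-burst firing rate (active-period rates do
    not change with age; total rates do, through down-state prevalence).
    Discontinuity relaxes with age: long silent gaps at P6-7 shorten through
    P10-11 and disappear in the juvenile groups. Oscillation depth and slow
    shared modulation (retinal-wave comodulation) are strongest early; fast
    pairwise correlation appears only in the juvenile groups. Frequencies,
    depths and correlation values are qualitative stand-ins, not measured
    quantities.
    """
    base = dict(n_units=16, n_mua=4, duration_ms=1_800_000, in_burst_rate_hz=5.0)
    presets: dict[str, dict] = {
        "P6_7": dict(
            regime="neonatal",
            active_duration_range=(2_000, 10_000),
            inter_event_range=(30_000, 60_000),
            oscillation_depth=0.6,
            slow_mod_var=0.05,
            shared_fast_corr=0.0,
        ),
        "P8_9": dict(
            regime="neonatal",
            active_duration_range=(2_000, 10_000),
            inter_event_range=(25_000, 50_000),
            oscillation_depth=0.6,
            slow_mod_var=0.05,
            shared_fast_corr=0.0,
        ),
        "P10_11": dict(
            regime="neonatal",
            active_duration_range=(2_000, 10_000),
            inter_event_range=(10_000, 30_000),
            oscillation_depth=0.4,
            slow_mod_var=0.05,
            shared_fast_corr=0.0,
        ),
        "P15_17": dict(
            regime="juvenile",
            oscillation_depth=0.2,
            slow_mod_var=0.05,
            shared_fast_corr=0.03,
        ),
        "P24": dict(
            regime="juvenile",
            oscillation_depth=0.0,
            slow_mod_var=0.05,
            shared_fast_corr=0.05,
        ),
    }
    if age_group not in presets:
        raise ValueError(f"unknown age group {age_group!r}; choose from {AGE_GROUPS}")
    kwargs = {**base, **presets[age_group], **overrides}
    if "coupling_weights" not in kwargs or kwargs["coupling_weights"] is None:
        # heterogeneous population coupling is present at every age: spread
        # the shared-gain weights so each cohort spans weak to strong coupling
        kwargs["coupling_weights"] = np.linspace(0.2, 1.0, kwargs["n_units"])
    return SyntheticConfig(**kwargs)
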