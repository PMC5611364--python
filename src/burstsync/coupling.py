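"""Population coupling: spike-triggered population rate, marginal-normalized.

For each good single unit, the summed raster of all other clusters in its
layer group (single + multi-unit) is smoothed with a 10 ms SD Gaussian and
averaged around that unit's spikes (the stPR, spike-triggered population
rate). Its zero-lag value measures how strongly the unit participates in
local population fluctuations ("choristers" high, "soloists" low). To make
the number comparable across recordings, stPR curves are also computed on
raster-marginal surrogates of the same layer-group raster; the peak of the
across-unit mean surrogate curve is the normalization constant, so a
coupling of 1 means "as coupled as expected from the raster marginals".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .raster import BinnedRaster, SpikeTrain, bin_spikes, single_units
from .surrogates import SurrogateSpec, child_rngs, raster_marginal_shuffle

__all__ = [
    "population_rate",
    "spike_triggered_rate",
    "stpr_curves",
    "normalized_coupling",
    "CouplingResult",
    "coupling_rate_relation",
]

DEFAULT_LAG_MS = 400
POP_SMOOTH_SD = 10.0


def population_rate(counts: np.ndarray, smooth_sd: float = POP_SMOOTH_SD) -> np.ndarray:
    """Gaussian-smoothed population rate from a summed 1 ms count vector.

    Units are spikes/ms; smoothing conserves total spike mass (up to edge
    truncation of the zero-padded convolution).
    """
    return gaussian_filter1d(np.asarray(counts, float), sigma=smooth_sd,
                             mode="constant", truncate=4.0)


def spike_triggered_rate(
    spike_times: np.ndarray,
    pop_trace: np.ndarray,
    lag_ms: int = DEFAULT_LAG_MS,
) -> np.ndarray:
    """Average of the population trace in +-lag_ms around each spike.

    Spikes whose window exits the recording are dropped. Returns a curve of
    length ``2*lag_ms + 1`` (lag 0 at the center), NaN-filled when no spike
    has a full window.
    """
    t = np.asarray(spike_times, np.int64)
    t = t[(t >= lag_ms) & (t < pop_trace.size - lag_ms)]
    if t.size == 0:
        return np.full(2 * lag_ms + 1, np.nan)
    offsets = np.arange(-lag_ms, lag_ms + 1)
    return pop_trace[t[:, None] + offsets[None, :]].mean(axis=0)


def _group_raster(units: Sequence[SpikeTrain], layer_group: str) -> tuple[BinnedRaster, list[int]]:
    members = [u for u in units if u.layer_group == layer_group]
    if len(members) < 2:
        raise ValueError(f"layer group {layer_group!r} needs >= 2 contributors")
    raster = bin_spikes(members, 1, binarize=True)
    su_rows = [i for i, u in enumerate(members) if u.unit_class == "single"]
    return raster, su_rows


def stpr_curves(
    raster: BinnedRaster,
    trigger_rows: Sequence[int],
    lag_ms: int = DEFAULT_LAG_MS,
    smooth_sd: float = POP_SMOOTH_SD,
) -> np.ndarray:
    """stPR curve for each trigger row of a binarized 1 ms group raster.

    The population trace for row ``i`` excludes that unit's own spikes
    (otherwise every curve carries a trivial self-peak at lag 0). Smoothing
    is linear, so the per-unit trace is the smoothed total minus the
    smoothed own raster.
    """
    total = raster.matrix.sum(axis=0).astype(float)
    smoothed_total = population_rate(total, smooth_sd)
    curves = np.empty((len(trigger_rows), 2 * lag_ms + 1))
    for k, i in enumerate(trigger_rows):
        own = population_rate(raster.matrix[i].astype(float), smooth_sd)
        trace = smoothed_total - own
        spikes = np.flatnonzero(raster.matrix[i])
        curves[k] = spike_triggered_rate(spikes, trace, lag_ms)
    return curves


@dataclass
class CouplingResult:
    """Per-unit population coupling for one layer group."""

    unit_ids: list[str]
    layer_group: str
    curves: np.ndarray  # (n_units, 2*lag+1) observed stPR, spikes/ms
    surrogate_mean_curve: np.ndarray
    normalization_constant: float  # peak of the mean surrogate stPR
    coupling: np.ndarray  # zero-lag stPR / constant
    lag_ms: int

    @property
    def mean_coupling(self) -> float:
        return float(np.nanmean(self.coupling))

    def lags(self) -> np.ndarray:
        return np.arange(-self.lag_ms, self.lag_ms + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(unit_id=self.unit_ids, layer_group=self.layer_group,
                 coupling=self.coupling)
        )


def normalized_coupling(
    units: Sequence[SpikeTrain],
    layer_group: str,
    spec: SurrogateSpec | None = None,
    n_surrogates: int = 10,
    lag_ms: int = DEFAULT_LAG_MS,
    smooth_sd: float = POP_SMOOTH_SD,
    statistic: str = "zero_lag",
) -> CouplingResult:
    """Marginal-normalized population coupling for one layer group.

    The raster (all clusters of the group, binarized at 1 ms) is shuffled
    ``n_surrogates`` times with the raster-marginal model; the normalization
    constant is the maximum over lags of the across-unit, across-surrogate
    mean stPR curve. Coupling is the observed zero-lag stPR divided by that
    constant (``statistic="curve_max"`` uses each observed curve's maximum
    instead).
    """
    spec = spec or SurrogateSpec(kind="raster_marginal")
    raster, su_rows = _group_raster(units, layer_group)
    if not su_rows:
        raise ValueError(f"no single units in layer group {layer_group!r}")
    obs = stpr_curves(raster, su_rows, lag_ms, smooth_sd)

    surr_curves = []
    for rng in child_rngs(spec.seed, n_surrogates):
        shuf = raster_marginal_shuffle(raster, None, spec, rng=rng)
        surr_curves.append(stpr_curves(shuf, su_rows, lag_ms, smooth_sd))
    surr_mean = np.nanmean(np.stack(surr_curves), axis=(0, 1))
    constant = float(np.nanmax(surr_mean))
    if not np.isfinite(constant) or constant <= 0:
        raise ValueError("degenerate surrogate stPR; cannot normalize")

    if statistic == "zero_lag":
        value = obs[:, lag_ms]
    elif statistic == "curve_max":
        value = np.nanmax(obs, axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    member_ids = [raster.unit_ids[i] for i in su_rows]
    return CouplingResult(
        unit_ids=member_ids,
        layer_group=layer_group,
        curves=obs,
        surrogate_mean_curve=surr_mean,
        normalization_constant=constant,
        coupling=value / constant,
        lag_ms=lag_ms,
    )


def coupling_rate_relation(
    result: CouplingResult | Sequence[CouplingResult],
    rates: pd.DataFrame,
) -> tuple[float, float]:
    """Pearson correlation between per-unit firing rate and coupling.

    ``rates`` is a `rate_summary` frame (total_rate_hz is used). Returns
    ``(r, p)``; r = 0 with p = NaN when coupling (or rate) has no variance,
    and p is NaN with fewer than 3 units.
    """
    results = [result] if isinstance(result, CouplingResult) else list(result)
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    merged = frame.merge(rates[["unit_id", "total_rate_hz"]], on="unit_id")
    merged = merged.dropna(subset=["coupling", "total_rate_hz"])
    x, y = merged["total_rate_hz"].to_numpy(), merged["coupling"].to_numpy()
    if len(merged) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0, float("nan")
    if len(merged) < 3:
        return float(np.corrcoef(x, y)[0, 1]), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)
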