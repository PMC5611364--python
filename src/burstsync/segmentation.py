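"""Down-state / active-period segmentation from total multi-unit activity.

Developing cortex spends most of its time in network silence ("down-states")
interrupted by multi-second active periods. Segmentation works on the tMUA
raster (1 ms spike sum over all clusters): the signal is smoothed with a
Gaussian kernel (SD 50 ms, truncated at +-4 SD, zero-padded edges); samples
where the smoothed signal falls below 10% of its peak, OR that lie inside a
gap of more than 50 ms between consecutive tMUA spikes, are marked down.
Active runs shorter than 50 ms are then reclassified as down-states.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .raster import BinnedRaster, SpikeTrain

__all__ = [
    "ActivePeriodSet",
    "detect_active_periods",
    "fraction_active",
    "rate_summary",
]


@dataclass
class ActivePeriodSet:
    """Sorted, non-overlapping half-open [start_ms, end_ms) active intervals.

    The complement within ``[0, recording_duration)`` is the down-state set.
    """

    intervals: np.ndarray  # (n, 2) int64
    recording_duration: int

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("empty or inverted interval")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals overlap or are unsorted")
            if iv[0, 0] < 0 or iv[-1, 1] > self.recording_duration:
                raise ValueError("interval outside recording")
        self.intervals = iv

    @property
    def n_periods(self) -> int:
        return self.intervals.shape[0]

    @property
    def total_active_ms(self) -> int:
        if not self.intervals.size:
            return 0
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, times_ms: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside an active period."""
        t = np.asarray(times_ms)
        if not self.intervals.size:
            return np.zeros(t.shape, dtype=bool)
        starts, ends = self.intervals[:, 0], self.intervals[:, 1]
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] < ends[idx[ok]]
        return out

    def mask(self, n_samples: int | None = None) -> np.ndarray:
        """Per-ms boolean active mask of length ``recording_duration``."""
        n = self.recording_duration if n_samples is None else n_samples
        m = np.zeros(n, dtype=bool)
        for s, e in self.intervals:
            m[s:min(e, n)] = True
        return m

    def restrict(self, other: "ActivePeriodSet") -> "ActivePeriodSet":
        """Intersection with another interval set (same recording)."""
        m = self.mask() & other.mask()
        return ActivePeriodSet(_mask_to_intervals(m), self.recording_duration)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.intervals, columns=["start_ms", "end_ms"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, recording_duration: int) -> "ActivePeriodSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["start_ms", "end_ms"]].to_numpy(np.int64), recording_duration)


def _mask_to_intervals(mask: np.ndarray) -> np.ndarray:
    """Runs of True in a boolean vector as (n, 2) half-open intervals."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros((0, 2), dtype=np.int64)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        ends = np.concatenate([ends, [m.size]])
    return np.column_stack([starts, ends]).astype(np.int64)


def detect_active_periods(
    tmua: BinnedRaster,
    smooth_sd: float = 50.0,
    peak_frac: float = 0.10,
    isi_gap: int = 50,
    min_active: int = 50,
    peak_percentile: float | None = None,
) -> ActivePeriodSet:
    """Segment a recording into active periods and down-states.

    Parameters
    ----------
    tmua : BinnedRaster
        tMUA at 1 ms bins (rows are summed if more than one).
    smooth_sd : float
        Gaussian smoothing SD in ms (default 50).
    peak_frac : float
        Down-state threshold as a fraction of the smoothed signal's peak
        (default 0.10).
    isi_gap : int
        Any gap between consecutive tMUA spikes longer than this (ms) is a
        down-state, exclusive of the bounding spikes' bins (default 50).
    min_active : int
        Active runs shorter than this (ms) are reclassified as down-states
        (default 50).
    peak_percentile : float, optional
        If given, "peak" is this percentile of the smoothed signal instead
        of the global maximum (robust variant; default uses the max).
    """
    if tmua.bin_width != 1:
        raise ValueError("down-state detection expects a 1 ms tMUA raster")
    counts = tmua.matrix.sum(axis=0).astype(float)
    n = counts.size
    if n == 0 or counts.sum() == 0:
        return ActivePeriodSet(np.zeros((0, 2), np.int64), n)

    smoothed = gaussian_filter1d(counts, sigma=smooth_sd, mode="constant", truncate=4.0)
    peak = (
        float(np.percentile(smoothed, peak_percentile))
        if peak_percentile is not None
        else float(smoothed.max())
    )
    down = smoothed < peak_frac * peak

    spike_bins = np.flatnonzero(counts > 0)
    gaps = np.diff(spike_bins)
    for i in np.flatnonzero(gaps > isi_gap):
        down[spike_bins[i] + 1 : spike_bins[i + 1]] = True
    # leading / trailing silence has no bounding ISI; treat like a gap
    if spike_bins[0] > isi_gap:
        down[: spike_bins[0]] = True
    if n - 1 - spike_bins[-1] > isi_gap:
        down[spike_bins[-1] + 1 :] = True

    active = ~down
    intervals = _mask_to_intervals(active)
    keep = (intervals[:, 1] - intervals[:, 0]) >= min_active
    return ActivePeriodSet(intervals[keep], n)


def fraction_active(periods: ActivePeriodSet) -> float:
    """Proportion of the recording occupied by active periods."""
    if periods.recording_duration <= 0:
        raise ValueError("zero-length recording")
    return periods.total_active_ms / periods.recording_duration


def rate_summary(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
) -> pd.DataFrame:
    """Per-unit firing rate over the whole recording and over active time only.

    Removing down-states asks whether units fire at similar rates *within*
    activations even when total rates differ by orders of magnitude.

    Returns a DataFrame with columns unit_id, layer_group, unit_class,
    n_spikes, total_rate_hz, active_rate_hz (NaN when active time is 0).
    """
    active_ms = periods.total_active_ms
    rows = []
    for u in units:
        n_active = int(periods.contains(u.spike_times).sum())
        total_rate = 1000.0 * u.n_spikes / u.recording_duration if u.recording_duration else 0.0
        active_rate = 1000.0 * n_active / active_ms if active_ms else float("nan")
        rows.append(
            dict(
                unit_id=u.unit_id,
                layer_group=u.layer_group,
                unit_class=u.unit_class,
                n_spikes=u.n_spikes,
                total_rate_hz=total_rate,
                active_rate_hz=active_rate,
            )
        )
    return pd.DataFrame(rows)
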