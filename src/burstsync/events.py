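"""Event participation: how many single-units co-fire in short windows.

An "event size" is the number of single-units with at least one spike in a
20 or 100 ms window. Only windows lying entirely inside active periods are
considered, and only windows containing more than one spike can register an
event; the probability of a size-k event is the number of qualifying windows
of size k divided by the total number of in-active windows. Recordings with
more than 12 single units are equalized by randomly selecting 12 units,
repeating 20 times and averaging the probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import SpikeTrain, single_units
from .segmentation import ActivePeriodSet

__all__ = [
    "window_spike_counts",
    "event_size_distribution",
    "EventSizeDistribution",
    "deviation_index",
    "threshold_synchrony",
]


def window_spike_counts(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
    window_ms: int,
    step_ms: int = 1,
) -> np.ndarray:
    """Per-unit spike counts for every window inside an active period.

    Windows of ``window_ms`` are slid in steps of ``step_ms`` within each
    active interval; windows straddling a boundary are excluded entirely.
    Returns a (n_units, n_windows) integer matrix (empty second axis when no
    interval can hold a full window).
    """
    units = list(units)
    counts = []
    for s, e in periods.intervals:
        if e - s < window_ms:
            continue
        starts = np.arange(s, e - window_ms + 1, step_ms)
        block = np.empty((len(units), starts.size), dtype=np.int32)
        for i, u in enumerate(units):
            t = u.spike_times
            block[i] = np.searchsorted(t, starts + window_ms) - np.searchsorted(t, starts)
        counts.append(block)
    if not counts:
        return np.zeros((len(units), 0), dtype=np.int32)
    return np.concatenate(counts, axis=1)


@dataclass
class EventSizeDistribution:
    """Probability of each event size, averaged over unit subsamples."""

    window_ms: int
    probabilities: dict[int, float]  # size k -> mean fraction of windows
    n_windows_total: int
    subsample_size: int
    n_subsample_repeats: int
    threshold_probability: float = float("nan")  # synchrony-threshold prob

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, name="probability").sort_index()


def _size_histogram(counts: np.ndarray, max_size: int) -> np.ndarray:
    """Histogram of event sizes over windows with >1 total spike."""
    qualifying = counts.sum(axis=0) > 1
    sizes = (counts[:, qualifying] > 0).sum(axis=0)
    return np.bincount(sizes, minlength=max_size + 1)


def event_size_distribution(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
    window_ms: int = 20,
    step_ms: int = 1,
    subsample_size: int = 12,
    n_subsample_repeats: int = 20,
    rng: np.random.Generator | None = None,
    counts: np.ndarray | None = None,
) -> EventSizeDistribution:
    """Event-size probabilities for the good single units of a recording.

    With more than ``subsample_size`` single units, probabilities are the
    mean over ``n_subsample_repeats`` random subsets of that size; with at
    most ``subsample_size`` units all of them are used in a single pass.
    ``counts`` may carry a precomputed `window_spike_counts` matrix (it must
    match ``units`` row for row).

    Probabilities are fractions of *all* in-active windows, so sizes 2..n
    need not sum to 1 (windows with <=1 spike register no event).
    """
    sus = single_units(units)
    if counts is None:
        counts = window_spike_counts(sus, periods, window_ms, step_ms)
    elif counts.shape[0] != len(sus):
        raise ValueError("precomputed counts do not match the single-unit set")
    n_windows = counts.shape[1]
    n_units = len(sus)

    if n_units <= subsample_size:
        draws = [np.arange(n_units)]
    else:
        if rng is None:
            rng = np.random.default_rng()
        draws = [
            rng.choice(n_units, size=subsample_size, replace=False)
            for _ in range(n_subsample_repeats)
        ]

    k_max = min(n_units, subsample_size)
    hist = np.zeros(k_max + 1, dtype=float)
    for idx in draws:
        hist += _size_histogram(counts[idx], k_max)
    hist /= len(draws)

    probs = {
        k: (hist[k] / n_windows if n_windows else 0.0) for k in range(2, k_max + 1)
    }
    return EventSizeDistribution(
        window_ms=window_ms,
        probabilities=probs,
        n_windows_total=n_windows,
        subsample_size=subsample_size,
        n_subsample_repeats=len(draws),
    )


def deviation_index(
    observed: EventSizeDistribution | dict[int, float],
    null: EventSizeDistribution | dict[int, float],
) -> pd.Series:
    """Bounded observed-vs-null contrast (P - P_null) / (P + P_null).

    +1 means the size occurs only in the observed data, -1 only in the null;
    0 means equal probability. Undefined (NaN) when both probabilities are 0.
    """
    p_obs = observed.probabilities if isinstance(observed, EventSizeDistribution) else observed
    p_null = null.probabilities if isinstance(null, EventSizeDistribution) else null
    keys = sorted(set(p_obs) | set(p_null))
    out = {}
    for k in keys:
        a, b = p_obs.get(k, 0.0), p_null.get(k, 0.0)
        out[k] = (a - b) / (a + b) if (a + b) > 0 else float("nan")
    return pd.Series(out, name="deviation_index")


def threshold_synchrony(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
    window_ms: int = 20,
    threshold_frac: float = 0.25,
    inclusive: bool = False,
    subsample_size: int = 12,
    n_subsample_repeats: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability of highly synchronous windows.

    Fraction of non-overlapping ``window_ms`` bins inside active periods in
    which the participating fraction of single-units exceeds
    ``threshold_frac`` (strictly by default, matching ">25% active in 20 ms
    bins"; set ``inclusive`` for the ">=50% in 100 ms" variant). The >1-spike
    rule applies as for event sizes. Subsampling to 12 units mirrors
    `event_size_distribution`.
    """
    sus = single_units(units)
    counts = window_spike_counts(sus, periods, window_ms, step_ms=window_ms)
    n_windows = counts.shape[1]
    if n_windows == 0:
        return 0.0
    n_units = len(sus)
    if n_units <= subsample_size:
        draws = [np.arange(n_units)]
    else:
        if rng is None:
            rng = np.random.default_rng()
        draws = [
            rng.choice(n_units, size=subsample_size, replace=False)
            for _ in range(n_subsample_repeats)
        ]
    probs = []
    for idx in draws:
        sub = counts[idx]
        qualifying = sub.sum(axis=0) > 1
        frac = (sub > 0).sum(axis=0) / len(idx)
        hit = (frac >= threshold_frac) if inclusive else (frac > threshold_frac)
        probs.append((hit & qualifying).sum() / n_windows)
    return float(np.mean(probs))
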