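"""Null models for spike rasters: spike-time jitter and the raster-marginal shuffle.

Two complementary surrogates are used throughout:

* **Jitter** displaces every spike by a uniform random offset within
  +-``jitter_halfwidth`` ms (default 1000), constrained to land inside an
  active period. This destroys fine spike timing while preserving per-unit
  spike counts and the slow rate envelope, and is the reference for "what
  would random firing at locally appropriate rates look like".

* **Raster-marginal shuffle** operates on the binarized raster and applies
  checkerboard (2x2) swaps that exactly conserve every unit's spike count
  and every time bin's population count. It preserves the population-level
  temporal structure (how many cells fire in each bin) while randomizing
  *which* cells fire, and is restricted to swaps between units of the same
  layer group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .raster import BinnedRaster, SpikeTrain
from .segmentation import ActivePeriodSet

__all__ = [
    "SurrogateSpec",
    "jitter_spikes",
    "raster_marginal_shuffle",
    "surrogate_ensemble",
    "EnsembleResult",
    "child_rngs",
]


@dataclass
class SurrogateSpec:
    """Parameters of a null model plus its seed.

    ``swap_multiplier`` sets the number of attempted checkerboard swaps per
    matrix entry of 1 (a standard burn-in for swap randomization).
    """

    kind: str = "jitter"  # {"jitter", "raster_marginal"}
    jitter_halfwidth: int = 1000
    n_repeats: int = 100
    swap_multiplier: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("jitter", "raster_marginal"):
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.jitter_halfwidth <= 0:
            raise ValueError("jitter_halfwidth must be > 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators deterministically derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Jitter
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 1000


def jitter_spikes(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
    spec: SurrogateSpec | None = None,
    rng: np.random.Generator | None = None,
    boundary: str = "wrap",
    outside: str = "error",
) -> list[SpikeTrain]:
    """Jitter every spike uniformly within +-halfwidth, staying in active time.

    Per-unit spike counts are conserved and the output support is exactly
    the active-period union. Spikes already outside all active periods are a
    hard error: they signal a segmentation mismatch, not a jitterable raster.

    Boundary handling (``boundary``):

    * ``"wrap"`` (default) — the displaced time wraps circularly within the
      spike's containing active period. This keeps the jittered times of a
      homogeneous process exactly uniform over the period, so the null is
      distribution-preserving for Poisson firing. (Re-drawing displacements
      until they land inside the period instead *conditions* on the
      boundary and piles density unevenly near period edges — a shared
      non-uniformity across units that inflates co-activation under the
      null; wrap avoids that bias.)
    * ``"redraw"`` — re-draw an exiting displacement up to 1000 times, then
      clamp to the containing period's edge. A displaced spike may land in
      any active period. Kept for comparison with the conditioning variant.

    ``outside`` sets the policy for spikes already outside all active
    periods: ``"error"`` (default — they signal that the segmentation does
    not belong to this raster), ``"keep"`` (leave them untouched; apt when
    periods were *detected* from this raster, where stray spikes in
    down-states are expected), or ``"drop"``.
    """
    spec = spec or SurrogateSpec(kind="jitter")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
    if boundary not in ("wrap", "redraw"):
        raise ValueError(f"unknown boundary mode {boundary!r}")
    hw = spec.jitter_halfwidth
    starts = periods.intervals[:, 0] if periods.intervals.size else np.empty(0, np.int64)
    ends = periods.intervals[:, 1] if periods.intervals.size else np.empty(0, np.int64)

    out = []
    for u in units:
        t = u.spike_times
        if t.size == 0:
            out.append(u.with_times(t))
            continue
        inside = periods.contains(t)
        fixed = np.empty(0, np.int64)
        if not inside.all():
            if outside == "error":
                bad = t[~inside][0]
                raise ValueError(
                    f"unit {u.unit_id}: spike at {bad} ms outside all active "
                    "periods; segmentation does not match this raster"
                )
            if outside == "keep":
                fixed = t[~inside]
            elif outside != "drop":
                raise ValueError(f"unknown outside policy {outside!r}")
            t = t[inside]
        if t.size == 0:
            out.append(u.with_times(fixed))
            continue
        d = rng.integers(-hw, hw + 1, size=t.size)
        if boundary == "wrap":
            idx = np.searchsorted(starts, t, side="right") - 1
            s, length = starts[idx], ends[idx] - starts[idx]
            new = s + (t - s + d) % length
        else:
            new = t.copy()
            cand = t + d
            ok = _in_any(cand, starts, ends)
            new[ok] = cand[ok]
            pending = np.flatnonzero(~ok)
            for _ in range(_MAX_REDRAWS):
                if pending.size == 0:
                    break
                cand = t[pending] + rng.integers(-hw, hw + 1, size=pending.size)
                ok = _in_any(cand, starts, ends)
                new[pending[ok]] = cand[ok]
                pending = pending[~ok]
            if pending.size:
                # clamp survivors to their containing period's edges
                idx = np.searchsorted(starts, t[pending], side="right") - 1
                lo, hi = starts[idx], ends[idx] - 1
                new[pending] = np.clip(
                    t[pending] + rng.integers(-hw, hw + 1, pending.size), lo, hi
                )
        out.append(u.with_times(np.concatenate([new, fixed])))
    return out


def _in_any(t: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(t.shape, bool)
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    res = np.zeros(t.shape, bool)
    res[ok] = t[ok] < ends[idx[ok]]
    return res


# ---------------------------------------------------------------------------
# Raster-marginal shuffle
# ---------------------------------------------------------------------------


@njit(cache=True)
def _checkerboard_swaps(mat, rows, cols, pick_a, pick_b):  # pragma: no cover
    """Attempt checkerboard swaps at precomputed random pairs of ones.

    ``rows``/``cols`` list the coordinates of the ones; a swap moves the two
    ones at (r1,c1),(r2,c2) to (r1,c2),(r2,c1) when the latter cells are
    empty, conserving all row and column sums.
    """
    n_swapped = 0
    for k in range(pick_a.size):
        a = pick_a[k]
        b = pick_b[k]
        r1, c1 = rows[a], cols[a]
        r2, c2 = rows[b], cols[b]
        if r1 == r2 or c1 == c2:
            continue
        if mat[r1, c2] == 0 and mat[r2, c1] == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            cols[a] = c2
            cols[b] = c1
            n_swapped += 1
    return n_swapped


def raster_marginal_shuffle(
    raster: BinnedRaster,
    layer_groups: dict[str, str] | None = None,
    spec: SurrogateSpec | None = None,
    rng: np.random.Generator | None = None,
) -> BinnedRaster:
    """Marginal-preserving shuffle of a binary raster within layer groups.

    Every unit's row sum and, within each layer group, every bin's column
    sum are conserved exactly. ``layer_groups`` maps unit_id -> group label;
    omitted units (or ``None``) form a single group. A group with a single
    unit admits no legal swap and is returned unchanged with a warning.
    """
    spec = spec or SurrogateSpec(kind="raster_marginal")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
    mat = np.asarray(raster.matrix)
    if mat.size and mat.max() > 1:
        raise ValueError("raster_marginal_shuffle requires a binarized raster")
    out = mat.astype(np.uint8).copy()

    if layer_groups is None:
        groups: dict[str, list[int]] = {"all": list(range(raster.n_units))}
    else:
        groups = {}
        for i, uid in enumerate(raster.unit_ids):
            groups.setdefault(layer_groups.get(uid, "all"), []).append(i)

    for label, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"layer group {label!r} has a single unit; no swaps possible",
                stacklevel=2,
            )
            continue
        sub = out[idx]
        rows, cols = np.nonzero(sub)
        m = rows.size
        if m < 2:
            continue
        n_attempts = spec.swap_multiplier * m
        pick_a = rng.integers(0, m, size=n_attempts)
        pick_b = rng.integers(0, m, size=n_attempts)
        _checkerboard_swaps(sub, rows.astype(np.int64), cols.astype(np.int64),
                            pick_a.astype(np.int64), pick_b.astype(np.int64))
        out[idx] = sub
    return BinnedRaster(out, raster.bin_width, list(raster.unit_ids), raster.bin_origin)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Per-draw statistic values with their mean and central 95% interval."""

    values: np.ndarray  # (n_repeats, ...) stacked statistic values
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]


def surrogate_ensemble(
    base,
    spec: SurrogateSpec,
    statistic: Callable,
    periods: ActivePeriodSet | None = None,
    layer_groups: dict[str, str] | None = None,
) -> EnsembleResult:
    """Apply a statistic to ``n_repeats`` independent surrogate draws.

    ``base`` is a SpikeTrain collection (jitter) or a binarized BinnedRaster
    (raster_marginal); each draw uses an independently derived child seed, so
    the ensemble is reproducible from ``spec.seed`` alone. The statistic must
    be a pure function returning a scalar or ndarray; returns per-draw values
    plus their mean and central 95% interval across draws.
    """
    rngs = child_rngs(spec.seed, spec.n_repeats)
    values = []
    for rng in rngs:
        if spec.kind == "jitter":
            if periods is None:
                raise ValueError("jitter ensemble requires active periods")
            draw = jitter_spikes(base, periods, spec, rng=rng)
        else:
            draw = raster_marginal_shuffle(base, layer_groups, spec, rng=rng)
        values.append(np.asarray(statistic(draw), dtype=float))
    arr = np.stack(values)
    return EnsembleResult(
        values=arr,
        mean=arr.mean(axis=0),
        lo=np.percentile(arr, 2.5, axis=0),
        hi=np.percentile(arr, 97.5, axis=0),
    )
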