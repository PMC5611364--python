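"""Neural "word" statistics: occurrence of unique binary firing vectors.

A word is the set of single-units jointly active in one non-overlapping
20 ms bin; only words of 3+ units are counted, and each bin contributes at
most one word (its full active set). Observed word probabilities are
compared with the jitter null (random firing at locally appropriate rates)
and with the raster-marginal null (population-rate structure intact, unit
identities randomized); the bounded per-word occurrence index
(P_obs - P_null)/(P_obs + P_null) summarizes the comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import BinnedRaster, SpikeTrain, bin_spikes, single_units
from .segmentation import ActivePeriodSet
from .surrogates import SurrogateSpec, child_rngs, jitter_spikes, raster_marginal_shuffle

__all__ = [
    "extract_words",
    "word_probabilities",
    "word_occurrence_index",
    "word_table",
    "WORD_BIN_MS",
    "MIN_WORD_SIZE",
]

WORD_BIN_MS = 20
MIN_WORD_SIZE = 3

Word = frozenset  # of unit_ids


def _active_bin_mask(periods: ActivePeriodSet, n_bins: int, bin_width: int) -> np.ndarray:
    """Bins lying entirely inside an active period."""
    starts = bin_width * np.arange(n_bins)
    mask = np.zeros(n_bins, dtype=bool)
    for s, e in periods.intervals:
        lo = int(np.ceil(s / bin_width))
        hi = (e - bin_width) // bin_width + 1
        mask[max(lo, 0) : max(hi, 0)] = True
    return mask & (starts + bin_width <= periods.recording_duration)


def extract_words(
    source: Sequence[SpikeTrain] | BinnedRaster,
    periods: ActivePeriodSet,
    bin_ms: int = WORD_BIN_MS,
    min_size: int = MIN_WORD_SIZE,
) -> tuple[Counter, int]:
    """Count word occurrences in non-overlapping bins within active periods.

    ``source`` is either a spike-train collection (its single units are
    binarized at ``bin_ms``) or an already-binarized BinnedRaster whose rows
    are all single units. Returns ``(Counter{word: occurrences}, n_bins)``
    where ``n_bins`` is the total number of in-active bins (the probability
    denominator). Bins with fewer than ``min_size`` active units contribute
    no word.
    """
    if isinstance(source, BinnedRaster):
        raster = source.binarized()
    else:
        raster = bin_spikes(single_units(source), bin_ms, binarize=True)
    mask = _active_bin_mask(periods, raster.n_bins, raster.bin_width)
    mat = raster.matrix[:, mask].astype(bool)
    ids = np.array(raster.unit_ids, dtype=object)
    words: Counter = Counter()
    sizes = mat.sum(axis=0)
    for j in np.flatnonzero(sizes >= min_size):
        words[frozenset(ids[mat[:, j]])] += 1
    return words, int(mask.sum())


def word_probabilities(words: Counter, n_bins: int) -> pd.DataFrame:
    """Occurrence probability per word type (occurrences / in-active bins)."""
    rows = [
        dict(
            word="+".join(sorted(w)),
            units=w,
            size=len(w),
            occurrences=c,
            probability=c / n_bins if n_bins else 0.0,
        )
        for w, c in sorted(words.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["word", "units", "size", "occurrences", "probability"])


def word_occurrence_index(
    observed: Mapping[Word, float],
    null: Mapping[Word, float],
) -> tuple[pd.Series, float]:
    """Per-word occurrence index and its mean over the union of word types.

    Index = (P_obs - P_null)/(P_obs + P_null): +1 for words seen only in the
    observed data, -1 for words seen only under the null. The dataset
    summary is the mean over all word types. Probabilities may be raw
    occurrence counts as long as observed and null share a denominator.
    """
    keys = set(observed) | set(null)
    idx = {}
    for w in keys:
        a, b = observed.get(w, 0.0), null.get(w, 0.0)
        if a + b > 0:
            idx["+".join(sorted(w))] = (a - b) / (a + b)
    series = pd.Series(idx, name="occurrence_index").sort_index()
    return series, float(series.mean()) if len(series) else float("nan")


def _prob_map(words: Counter, n_bins: int) -> dict[Word, float]:
    return {w: c / n_bins for w, c in words.items()} if n_bins else {}


def word_table(
    units: Sequence[SpikeTrain],
    periods: ActivePeriodSet,
    jitter_spec: SurrogateSpec | None = None,
    marginal_spec: SurrogateSpec | None = None,
    n_null_repeats: int = 10,
    bin_ms: int = WORD_BIN_MS,
    min_size: int = MIN_WORD_SIZE,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full word analysis: observed vs jitter and raster-marginal nulls.

    Per-word null probabilities in the table are averaged over
    ``n_null_repeats`` surrogate draws; the summary mean occurrence indices
    are computed per draw and then averaged (a multi-draw average contains
    more distinct word *types* than any single realization, which would
    drag the mean index negative even for structureless data). Words are
    defined over good single-units only; multi-unit clusters participate in
    the marginal swaps (they constrain the within-layer population counts)
    but never contribute to word identity.

    Returns ``(table, means)`` where ``table`` has one row per word type
    with observed and null probabilities and both indices, and ``means``
    maps null kind -> mean occurrence index.
    """
    sus = single_units(units)
    obs_words, n_bins = extract_words(sus, periods, bin_ms, min_size)
    obs = _prob_map(obs_words, n_bins)

    null_draws: dict[str, list[Counter]] = {}
    if jitter_spec is not None:
        draws = []
        for rng in child_rngs(jitter_spec.seed, n_null_repeats):
            jit = jitter_spikes(sus, periods, jitter_spec, rng=rng, outside="keep")
            w, _ = extract_words(jit, periods, bin_ms, min_size)
            draws.append(w)
        null_draws["jitter"] = draws
    if marginal_spec is not None:
        raster = bin_spikes(units, bin_ms, binarize=True)
        layer_map = {u.unit_id: u.layer_group for u in units}
        su_ids = {u.unit_id for u in sus}
        draws = []
        for rng in child_rngs(marginal_spec.seed, n_null_repeats):
            shuf = raster_marginal_shuffle(raster, layer_map, marginal_spec, rng=rng)
            keep = [i for i, uid in enumerate(shuf.unit_ids) if uid in su_ids]
            sub = BinnedRaster(shuf.matrix[keep], bin_ms,
                               [shuf.unit_ids[i] for i in keep])
            w, _ = extract_words(sub, periods, bin_ms, min_size)
            draws.append(w)
        null_draws["raster_marginal"] = draws
    nulls: dict[str, dict[Word, float]] = {}
    for kind, draws in null_draws.items():
        acc: Counter = Counter()
        for w in draws:
            acc.update(w)
        nulls[kind] = {w: c / (len(draws) * n_bins) for w, c in acc.items()}

    all_words = set(obs)
    for m in nulls.values():
        all_words |= set(m)
    rows = []
    for w in sorted(all_words, key=lambda w: (-obs.get(w, 0.0), sorted(w))):
        row = dict(
            word="+".join(sorted(w)),
            size=len(w),
            prob_observed=obs.get(w, 0.0),
        )
        for kind, m in nulls.items():
            p = m.get(w, 0.0)
            row[f"prob_{kind}"] = p
            tot = row["prob_observed"] + p
            row[f"index_{kind}"] = (row["prob_observed"] - p) / tot if tot else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    # summary means are per-draw (observed vs one surrogate realization,
    # averaged over draws): comparing against pooled multi-draw probabilities
    # instead would inflate the null's word-type richness and bias the mean
    means = {
        kind: float(
            np.mean(
                [
                    word_occurrence_index(obs, _prob_map(d, n_bins))[1]
                    for d in draws
                ]
            )
        )
        for kind, draws in null_draws.items()
    }
    return table, means
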