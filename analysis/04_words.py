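#!/usr/bin/env python
"""Neural-word occurrence vs the jitter and raster-marginal nulls.

Words are the sets of 3+ single-units co-active in non-overlapping 20 ms
bins within active periods. Against the jitter null, a positive mean
occurrence index says specific unit combinations recur above what firing
rates predict; against the raster-marginal null (which preserves each bin's
population count), an index near or below zero says that excess is carried
by population-wide timing, not by preferential pairings.
"""

from pathlib import Path

import pandas as pd

from burstsync.raster import load_spike_table
from burstsync.segmentation import ActivePeriodSet
from burstsync.surrogates import SurrogateSpec
from burstsync.synthetic import AGE_GROUPS
from burstsync.words import word_table

SEED = 71
N_NULL = 10

root = Path(__file__).resolve().parent.parent / "results"
rows = []
for i, age in enumerate(AGE_GROUPS):
    units = load_spike_table(root / "cohort" / f"{age}.tsv")
    duration = max(u.recording_duration for u in units)
    periods = ActivePeriodSet.from_tsv(
        root / "cohort" / f"{age}.detected_active_periods.tsv", duration
    )
    table, means = word_table(
        units, periods,
        jitter_spec=SurrogateSpec("jitter", seed=SEED + 2 * i),
        marginal_spec=SurrogateSpec("raster_marginal", seed=SEED + 2 * i + 1),
        n_null_repeats=N_NULL,
    )
    table.to_csv(root / "cohort" / f"{age}.words.tsv", sep="\t", index=False)
    rows.append(dict(age_group=age,
                     n_word_types=int((table.prob_observed > 0).sum()),
                     mean_index_jitter=means.get("jitter"),
                     mean_index_marginal=means.get("raster_marginal")))

summary = pd.DataFrame(rows)
summary.to_csv(root / "words_by_age.tsv", sep="\t", index=False)
print(summary.round(3).to_string(index=False))
print(
    "\nmean index vs jitter > 0 at every age would indicate word recurrence "
    "above rate expectations; the marginal control near 0 attributes it to "
    "population-wide timing."
)
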