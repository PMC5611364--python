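#!/usr/bin/env python
"""Simulate one synthetic recording per age-group preset (the 'cohort').

Writes a spike table plus ground-truth sidecars for each age group under
results/cohort/. Downstream analysis scripts (02-06) read these tables, so
the whole analysis chain runs off plain-text artifacts. 15 minutes per
recording keeps the cohort light while leaving thousands of spikes per unit
in the continuous regimes.
"""

from pathlib import Path

from burstsync.raster import write_spike_table
from burstsync.synthetic import AGE_GROUPS, generate_raster, regime_presets

BASE_SEED = 7
DURATION_MS = 900_000  # 15 min

out_dir = Path(__file__).resolve().parent.parent / "results" / "cohort"
out_dir.mkdir(parents=True, exist_ok=True)

for i, age in enumerate(AGE_GROUPS):
    cfg = regime_presets(age, seed=BASE_SEED + i, duration_ms=DURATION_MS)
    units, truth = generate_raster(cfg)
    write_spike_table(out_dir / f"{age}.tsv", units)
    truth.schedule.to_tsv(out_dir / f"{age}.true_active_periods.tsv")
    cfg.to_json(out_dir / f"{age}.config.json")
    n_spikes = sum(u.n_spikes for u in units)
    print(
        f"{age}: {len(units)} clusters, {n_spikes} spikes, "
        f"planted duty cycle {cfg.duty_cycle:.3f}"
    )

print(f"\ncohort written to {out_dir}")
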