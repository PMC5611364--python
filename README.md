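# burstsync

Spike-train synchrony statistics for developing cortical networks.

Before eye-opening, spontaneous activity in rodent visual cortex is
discontinuous: multi-second bursts of firing driven by retinal waves,
separated by tens of seconds of network silence ("down-states"). Whether the
firing *inside* those bursts is hyper-synchronous — as naive models of the
immature, weakly inhibited network would predict — or already shows
adult-like fine structure is a quantitative question about spike-train
statistics. `burstsync` implements the analysis chain needed to answer it
from spike-sorted extracellular recordings, together with a ground-truthed
synthetic raster generator so every stage can be exercised and validated
without animal data.

The package is aimed at systems/developmental neuroscientists working with
sorted spike trains (phy/KlustaSuite-style output or a plain spike table).

## What it computes

Given per-unit spike times (ms resolution) with layer-group and unit-class
labels:

1. **Down-state segmentation.** The total multi-unit activity (tMUA, the
   per-ms spike sum over all clusters) is smoothed with a Gaussian kernel
   (SD 50 ms); samples where the smoothed signal falls below 10% of its peak,
   or inside inter-spike gaps > 50 ms, are down-states; active runs < 50 ms
   are reclassified down. Firing rates are reported for the total recording
   and for active periods only.
2. **Event participation.** The number of single-units with ≥ 1 spike in
   sliding 20 / 100 ms windows within active periods, as a probability per
   event size *k* (12-unit random subsamples × 20 repeats equalize unit
   counts), plus threshold-synchrony probabilities (> 25% of units in 20 ms
   bins; ≥ 50% in 100 ms bins).
3. **Neural words.** Unique binary firing vectors (sets of ≥ 3 co-active
   single-units per non-overlapping 20 ms bin) and their occurrence
   probabilities.
4. **Pairwise spike-rate correlations.** Pearson correlation of spike trains
   convolved with a zero-sum difference-of-Gaussians kernel

   r_ij = corr( k ∗ s_i , k ∗ s_j ),  k(t) = N(0, J²) − N(0, (4J)²),  J = 20 ms,

   which cancels slow rate comodulation and isolates synchrony near the
   rapid timescale; with an integration-window sweep J ∈ {20, 100, 400} ms
   and an N = 12 subsample control for the −1/(N−1) correlation floor.
5. **Population coupling.** The spike-triggered population rate (stPR): the
   layer-group spike sum (own spikes excluded) smoothed at 10 ms SD and
   averaged ± 400 ms around each of a unit's spikes; the zero-lag value is
   normalized by the peak of the same measure on raster-marginal surrogates.

Two null models calibrate everything:

* **jitter** — each spike displaced uniformly within ± 1 s, constrained to
  active periods (circular wrap at period boundaries), repeated 100× for
  mean and 95% intervals. Destroys fine timing, preserves counts and the
  slow rate envelope. Observed-vs-null contrasts use the bounded deviation
  index (P − P_jitt)/(P + P_jitt).
* **raster marginal** — checkerboard (2×2) swaps on the binarized raster,
  restricted to units of the same layer group, exactly conserving every
  unit's spike count and every bin's within-group population count.

The `synthetic` module generates rasters with planted structure —
active/silent schedules (2–10 s bursts every 30–60 s in the neonatal regime),
oscillation-locked firing, a shared multiplicative gain calibrated to a
target 20 ms-scale pairwise count correlation, per-unit coupling weights,
and scheduled co-firing "words" — and returns the ground truth alongside,
so every analysis stage has an oracle.

## Worked example

```python
import numpy as np
from burstsync import (
    regime_presets, generate_raster, total_mua, detect_active_periods,
    fraction_active, rate_summary, build_kernel, pairwise_correlations,
    window_sweep, single_units,
)

cfg = regime_presets("P6_7", seed=7, duration_ms=900_000)  # 15 min neonatal
units, truth = generate_raster(cfg)
periods = detect_active_periods(total_mua(units))
print(f"fraction active: {fraction_active(periods):.3f}  "
      f"(planted duty cycle {cfg.duty_cycle:.3f})")

rates = rate_summary(units, periods).query("unit_class == 'single'")
print(f"mean rate: total {rates.total_rate_hz.mean():.2f} Hz, "
      f"active periods only {rates.active_rate_hz.mean():.2f} Hz")

res = pairwise_correlations(units, build_kernel(20, 4), periods, "active_only")
print(f"mean pair correlation (20 ms, active only): {res.mean_correlation:+.4f}")
print(window_sweep(units, periods, [20, 100, 400], "total").to_string(index=False))
```

prints

```
fraction active: 0.116  (planted duty cycle 0.118)
mean rate: total 0.57 Hz, active periods only 4.91 Hz
mean pair correlation (20 ms, active only): +0.0050
 rapid_sd_ms  slow_sd_ms restriction   mean_r  n_pairs
          20        80.0       total 0.006618      120
         100       400.0       total 0.050747      120
         400      1600.0       total 0.435022      120
```

The recording is 88% silence, so the total rate is an order of magnitude
below the in-burst rate. Fine-timescale (20 ms) correlations are near zero,
while at a 400 ms integration window the shared burst envelope dominates
(mean r ≈ 0.43): strong slow comodulation, little fine synchrony — the
signature this analysis chain is built to dissociate.

The numbered scripts under `analysis/` run the same chain over a simulated
five-age-group cohort (`01_simulate_cohort.py` … `06_coupling.py`) and write
tidy tables under `results/`. A `burstsync` CLI (`simulate`, `segment`,
`events`, `words`, `correlate`, `couple`, `run-all`) wraps the library for
shell use.

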