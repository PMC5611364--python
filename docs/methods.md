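# Methods

This note documents the models, parameters, numerical choices and known
limitations behind `burstsync`. All times are integer milliseconds; every
interval and bin is half-open, `[start, end)`; bin `i` of width `w` covers
`[origin + i·w, origin + (i+1)·w)`.

## Data model and QC

A recording is a collection of spike trains, one per sorted cluster, each
carrying a layer-group label (`L2_4` or `L5_6`) and a unit-class label
(`single` for well-isolated units, `multi` for multi-unit clusters). Spike
times are rounded to the nearest ms on load; ties at .5 round half away
from zero (any fixed rule would do; this one is documented and tested).
Layer assignment is an input label — identifying layers from LFP or visual
response latencies is upstream of this package.

Cluster quality uses the standard refractory criterion: the fraction of
inter-spike intervals strictly below 2 ms, undefined (NaN) below 2 spikes;
units are "good" when that fraction is below 1%.

Readers: a plain TSV spike table (`unit_id, time_ms, layer_group,
unit_class`, optional `#duration_ms=` header) that round-trips exactly, and
a phy/KlustaSuite-style directory (per-spike sample indices + cluster ids,
`cluster_group.tsv`, a `cluster_layers.tsv` sidecar, `params.py` with the
sampling rate). Sample indices are converted to ms and rounded.

## Down-state segmentation

The tMUA (per-ms spike sum over all clusters, single and multi) is smoothed
with a Gaussian kernel, SD 50 ms, truncated at ±4 SD, zero-padded at the
edges (this only affects the first/last ~200 ms). Down-states are the union
of (a) samples where the smoothed signal is below `peak_frac` = 0.10 of its
peak and (b) gaps between consecutive tMUA spikes longer than 50 ms,
exclusive of the bounding spikes' bins; leading/trailing silence longer
than the gap threshold is likewise down. The complement is taken first and
short active runs (< 50 ms) are then reclassified down — union, complement,
reclassify, in that order.

"Peak" defaults to the global maximum of the smoothed signal. Because a
maximum over ~10⁶ samples rides on the upper tail of the smoothing noise
and of any heavy-tailed rate modulation, a robust alternative
(`peak_percentile`) is exposed; the default stays at the maximum. Detection
on a raster paired with its own detected periods will typically leave a
handful of isolated spikes in down-states (their own contribution to the
smoothed signal is far below threshold) — this is expected, not an error,
and downstream analyses treat such spikes via an explicit policy (below).

Rates are reported as `total_rate` (spikes / recording duration) and
`active_rate` (spikes inside active periods / total active time, NaN when
there is no active time).

## Null models

**Jitter.** Every spike is displaced by an integer offset drawn uniformly
from ±`jitter_halfwidth` (default 1000 ms), constrained to active periods.
Boundary handling matters more than it looks: re-drawing offsets until the
spike lands inside a period *conditions* the displacement on the boundary,
which concentrates jittered density unevenly over ~1 s edge zones of every
period. Because that non-uniformity is shared across units, it inflates
co-activation under the null — on exactly-Poisson data the event-size
deviation index came out at −0.11 for mid-range sizes, several σ from 0.
The default is therefore circular wrap within the containing period
(`new = start + (t − start + d) mod length`), which maps the
uniform-given-counts distribution onto itself exactly, so the null is
distribution-preserving for Poisson firing; the re-draw variant remains
available (`boundary="redraw"`). Spikes outside all active periods raise by
default (`outside="error"`); callers pairing a raster with its own detected
segmentation pass `outside="keep"` (strays stay put) or `"drop"`.

**Raster marginal.** On the binarized raster, repeated 2×2 checkerboard
swaps — two ones at `(r1,c1),(r2,c2)` with the opposite corners empty move
to `(r1,c2),(r2,c1)` — exactly conserve every row sum and every column sum.
Swaps are restricted to unit pairs within the same layer group, so each
group's per-bin population count is conserved; multi-unit clusters
participate. The number of attempted swaps is `swap_multiplier` (default
10) × the number of ones, a standard burn-in for swap randomization; on a
3×4 toy matrix the sampler provably reaches the entire set of matrices
sharing the marginals (exhaustively enumerated in the tests). Counts > 1
per bin must be binarized first; this is a documented lossy step. A group
with a single unit admits no swap and is returned unchanged with a warning.

Surrogate ensembles derive one child seed per draw from a single
`SeedSequence`, report per-draw values plus the mean and central 95%
interval, and are bit-for-bit reproducible from the `SurrogateSpec` seed.

## Event participation

Windows of 20 or 100 ms slide in 1 ms steps within each active period;
windows straddling a boundary are excluded entirely. A window's event size
is the number of single-units with ≥ 1 spike; windows with ≤ 1 total spike
register no event. The probability of size *k* is (windows of size *k*) /
(all in-active windows) — the >1-spike rule filters the numerator, not the
denominator (computing it the other way is a one-line change; this is the
documented default). Recordings with more than 12 single units are
subsampled to 12, 20 times, and probabilities averaged. Threshold-synchrony
probabilities use non-overlapping bins (strictly > 25% of units in 20 ms;
≥ 50% in 100 ms).

The deviation index `(P − P_jitt)/(P + P_jitt)` is bounded in [−1, 1], NaN
when both probabilities vanish. Its Monte-Carlo noise is set by the number
of distinct co-activation episodes behind each size: overlapping windows
recount one episode up to 20 times, so a size observed in a few hundred
window positions carries index noise of ~±0.05–0.3. Null-consistency
checks therefore bound the index only for well-sampled sizes (≥ 10⁴
observed windows, where the noise floor is below 0.01); rarer sizes are
reported but cannot be held to a fixed tolerance at desk-scale data sizes.

## Neural words

A word is the full set of single-units active in one non-overlapping 20 ms
bin inside an active period, kept when it has ≥ 3 members; a bin
contributes exactly one word (supersets are not decomposed). Word
probability is occurrences / in-active bins. Per-word null probabilities
may be averaged over several surrogate draws, but the *mean* occurrence
index must be compared like with like: a pooled multi-draw null contains
more distinct word types than any single realization, and every null-only
type contributes a −1, dragging the mean strongly negative even for
structureless data (measured: −0.3 to −0.6 depending on the pool size).
`word_table` therefore computes summary means per draw and averages them;
the validation studies instead score the observed raster and each surrogate
against the same number of non-self draws, so the bias cancels exactly and
the observed mean can be tested against the surrogate-vs-surrogate 95%
interval. Words are defined over good single-units only; MUA rows
participate in the marginal swaps but never in word identity.

## Pairwise correlations

The kernel is a unit-mass Gaussian of SD `J` (default 20 ms) minus a
unit-mass Gaussian of SD `4J`, on a 1 ms grid truncated at ±4 slow SDs,
with the truncation residual subtracted so the weights sum to exactly zero.
A zero-DC kernel annihilates constants and any modulation much slower than
the slow lobe, making the Pearson correlation of the convolved trains a
fine-timescale synchrony measure. The kernel widths are interpreted as
Gaussian SDs; an FWHM reading is available via `width_mode="fwhm"`
(FWHM = 2.355 SD) because both conventions circulate for this measure.

For the active-only restriction, convolution runs over the full recording
and the correlation is computed over the samples inside active periods —
per-segment convolution would add an edge artifact at every boundary. Note
the converse cost: with integration windows approaching the burst duration,
the slow lobe reaches into the silence around each burst, so active-only
correlations at very large windows still carry some envelope signal.
Zero-variance traces yield NaN pairs. Traces are single-precision
(relative error ~10⁻⁴ at these lengths) with the Gram matrix accumulated
in double.

The jitter band repeats the full pair-correlation histogram on 100 jitter
surrogates and takes per-bin central 95% intervals (bin width 0.01 over
[−0.5, 0.5]). The window sweep re-runs the correlation at `J ∈ {20, 100,
400}` ms with slow = 4J (or a fixed slow width). `n_limited_mean` averages
the mean correlation over random 12-unit subsets, controlling the
−1/(N−1) floor of mean pairwise correlation.

## Population coupling

Per layer group, the binarized 1 ms raster is summed, smoothed with a 10 ms
SD Gaussian, and averaged in ±400 ms windows around each single unit's
spikes. The triggering unit's own spikes are excluded from its population
trace (smoothing is linear, so this is the smoothed total minus the
smoothed own raster); including them puts a kernel-shaped self-peak at lag
0 on every curve. The coupling statistic is the zero-lag stPR (curve-max is
exposed as an option) divided by a per-recording normalization constant:
the maximum over lags of the across-unit mean stPR on raster-marginal
surrogates of the same group raster, averaged over 10 surrogates. Feeding a
marginal-shuffled raster back through the pipeline yields mean coupling ≈ 1
by construction — the self-normalization calibration used in the tests.
A per-unit normalization variant is deliberately not the default; a single
per-recording constant keeps couplings comparable across units.

## Synthetic generator

Within active periods, unit *i* fires as a Bernoulli process on the 1 ms
grid with intensity

    λ_i(t) = r · (1 + d·cos(2π f t)) · max(0, 1 + w_i·g(t)),

`r` the in-burst rate (5 Hz default), `d` the oscillation depth at `f` = 15
Hz (a spindle-burst stand-in; no measured frequency is emulated), `w_i ∈
[0,1]` the unit's coupling weight and `g(t)` the shared gain fluctuation.
`g = (m_fast − 1) + (m_slow − 1)` with block-constant gamma multipliers
(mean 1): fast blocks of 20 ms whose variance is set in closed form so that
the 20 ms count correlation of fully coupled pairs equals the target
(`s² = ρ / (μ(1−ρ))`, `μ = 20 ms · r`; gamma keeps intensities non-negative
without clipping, so the calibration is exact — verified to ±0.01 at 30
min), and slow blocks of 1 s. Bernoulli thinning at 1 ms makes the mean
in-burst rate exact and allows at most one spike per unit per bin.

The neonatal schedule is a renewal process: gaps ~ U(30, 60) s alternating
with active periods ~ U(2, 10) s (duty cycle 6/51 ≈ 0.118); the juvenile
regime is a single active period. Planted words add one spike per member
unit in randomly chosen in-active 20 ms bins at a scheduled rate. MUA
clusters fire at 5× the unit rate (they pool several neurons) with full
gain weight.

Age presets (P6_7 … P24) share one in-burst rate — the developmental rate
gradient is carried entirely by down-state prevalence — with gaps
shortening across the neonatal groups and the juvenile groups continuous.
Oscillation depth decreases with age; fast shared correlation appears only
in the juvenile presets (0.03/0.05), matching the direction of the
developmental change in fine-timescale synchrony. The within-burst slow
gain variance is 0.05 in all presets, calibrated so that active-only mean
correlations at a 400 ms window stay moderate (~0.1–0.25) while
total-activity correlations at that window are dominated by the burst
envelope — the dissociation between slow comodulation and fine-timescale
synchrony that the window sweep is designed to expose. Preset coupling
weights spread over [0.2, 1] so each cohort spans weak to strong coupling.
Depth, frequency and correlation values are qualitative stand-ins, not
measurements.

What the generator does *not* emulate: refractoriness and bursting within
units, spatial (electrode-depth) structure, oscillation phase drift,
wave-to-wave variability in rate, non-stationarity across the session, and
spike-sorting artifacts (contamination, drift). Passing recovery tests on
this generator therefore demonstrates correctness of the statistics under
the stated model, not robustness to every property of real recordings.

## Validation studies and problem sizes

`burstsync.validation` fixes the canonical benchmark conditions used by
both the acceptance tests and `scripts/acceptance.py`: 1000 random binary
matrices for marginal exactness; 100 random rasters for jitter
conservation; null self-consistency on an exactly-Poisson neonatal raster
(12 single units + 4 MUA, 30 min, 50 jitter draws, 21 marginal draws);
brute-force oracle equivalence on a 6-unit, 20 s toy raster (naive loop
reimplementations of window counts, word extraction, convolution and stPR);
segmentation recovery and rate invariance on 30 min presets; correlation
recovery with planted ρ ∈ {0, 0.1, 0.3} (6 fully coupled units, 30 min) and
a 100-repeat jitter band; the slow-only dissociation (planted slow gain
variance 0.25, no oscillation, no fast correlation); and coupling-weight
recovery (24 units, one layer group so a single normalization constant
applies, weights 0…1, 30 min). These sizes keep each study in the seconds-
to-two-minutes range while leaving Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

- The event-size deviation index is uninformative for sparsely observed
  sizes (see above); analyses should report it alongside observation counts.
- The marginal sampler is a burn-in swap chain, not an exact uniform
  sampler of the marginal polytope; 10 swaps per one is ample for these
  densities but is a heuristic.
- Active-only correlations at integration windows comparable to the burst
  duration retain envelope leakage by construction.
- The phy reader supports the two-array layout plus sidecars only; no
  probe-geometry or waveform handling.
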