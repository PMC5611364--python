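"""Config-driven orchestration of the full analysis chain.

Stages run in a fixed order (segmentation -> rates -> event participation ->
words -> correlations -> coupling); each stage draws its randomness from a
child seed derived from the single run seed and the stage's fixed index, so
toggling one stage off never shifts another stage's random stream. Every
stage writes tidy TSV outputs plus a JSON manifest that fully reproduces
the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import correlations as corr
from . import coupling as cpl
from . import events as ev
from . import words as wd
from .raster import load_spike_table, single_units, total_mua, write_spike_table
from .segmentation import ActivePeriodSet, detect_active_periods, fraction_active, rate_summary
from .surrogates import SurrogateSpec
from .synthetic import generate_raster, regime_presets

log = logging.getLogger("burstsync")

# fixed stage indices for child-seed derivation
_STAGES = ("simulate", "segment", "events", "words", "correlate", "couple")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str | None = None  # spike_table path; None -> synthetic
    preset: str | None = None  # synthetic age-group preset
    output_dir: str = "burstsync_out"
    seed: int = 0
    stages: tuple[str, ...] = ("segment", "events", "words", "correlate", "couple")
    # segmentation
    smooth_sd_ms: float = 50.0
    peak_frac: float = 0.10
    isi_gap_ms: int = 50
    min_active_ms: int = 50
    # events
    event_windows_ms: tuple[int, ...] = (20, 100)
    subsample_size: int = 12
    n_subsample_repeats: int = 20
    # surrogates
    jitter_halfwidth_ms: int = 1000
    n_jitter_repeats: int = 100
    n_null_repeats: int = 10
    swap_multiplier: int = 10
    # correlations
    rapid_sd_ms: float = 20.0
    slow_multiplier: float = 4.0
    sweep_rapid_ms: tuple[float, ...] = (20, 100, 400)
    # coupling
    coupling_lag_ms: int = 400
    pop_smooth_sd_ms: float = 10.0
    synthetic_duration_ms: int | None = None

    def child_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty = valid)."""
    v = []
    if config.input_path is None and config.preset is None:
        v.append("either input_path or a synthetic preset is required")
    if config.rapid_sd_ms < 1:
        v.append("rapid_sd_ms must be >= 1 ms")
    if config.jitter_halfwidth_ms <= 0:
        v.append("jitter_halfwidth_ms must be > 0")
    if config.smooth_sd_ms <= 0:
        v.append("smooth_sd_ms must be > 0")
    if not 0 < config.peak_frac < 1:
        v.append("peak_frac must be in (0, 1)")
    if config.n_jitter_repeats < 1 or config.n_null_repeats < 1:
        v.append("surrogate repeat counts must be >= 1")
    if config.subsample_size < 2:
        v.append("subsample_size must be >= 2")
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        v.append(f"unknown stages: {sorted(unknown)}")
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict.

    All module outputs are written under ``config.output_dir`` together with
    ``manifest.json`` (parameters plus per-stage child seeds). Any stage
    failure aborts with the stage name in the exception; earlier outputs are
    retained.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {}

    # --- input ---
    if config.input_path is not None:
        units = load_spike_table(config.input_path)
        source = str(config.input_path)
    else:
        syn = regime_presets(
            config.preset,
            seed=config.child_seed("simulate"),
            **(
                {"duration_ms": config.synthetic_duration_ms}
                if config.synthetic_duration_ms
                else {}
            ),
        )
        units, truth = generate_raster(syn)
        write_spike_table(out / "synthetic_spikes.tsv", units)
        truth.schedule.to_tsv(out / "true_active_periods.tsv")
        syn.to_json(out / "synthetic_config.json")
        source = f"synthetic:{config.preset}"
    if not units:
        raise RuntimeError("stage input: no units loaded")
    duration = max(u.recording_duration for u in units)
    summary["n_units"] = len(units)
    summary["n_single_units"] = len(single_units(units))
    summary["duration_ms"] = duration

    periods: ActivePeriodSet | None = None
    rates: pd.DataFrame | None = None

    def _stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        if "segment" in config.stages:
            _stage("segment")
            periods = detect_active_periods(
                total_mua(units),
                smooth_sd=config.smooth_sd_ms,
                peak_frac=config.peak_frac,
                isi_gap=config.isi_gap_ms,
                min_active=config.min_active_ms,
            )
            periods.to_tsv(out / "active_periods.tsv")
            rates = rate_summary(units, periods)
            rates.to_csv(out / "rates.tsv", sep="\t", index=False)
            summary["fraction_active"] = fraction_active(periods)
            summary["n_active_periods"] = periods.n_periods
            summary["mean_total_rate_hz"] = float(
                rates.query("unit_class == 'single'")["total_rate_hz"].mean()
            )
            summary["mean_active_rate_hz"] = float(
                rates.query("unit_class == 'single'")["active_rate_hz"].mean()
            )

        needs_periods = {"events", "words", "correlate", "couple"} & set(config.stages)
        if needs_periods and periods is None:
            periods = detect_active_periods(total_mua(units))

        if "events" in config.stages:
            _stage("events")
            rng = np.random.default_rng(config.child_seed("events"))
            jspec = SurrogateSpec(
                "jitter",
                jitter_halfwidth=config.jitter_halfwidth_ms,
                seed=config.child_seed("events"),
            )
            rows = []
            sus = single_units(units)
            from .surrogates import jitter_spikes

            for window in config.event_windows_ms:
                obs = ev.event_size_distribution(
                    sus, periods, window, subsample_size=config.subsample_size,
                    n_subsample_repeats=config.n_subsample_repeats, rng=rng,
                )
                jit_units = jitter_spikes(sus, periods, jspec, outside="keep",
                                          rng=np.random.default_rng(jspec.seed + window))
                jit = ev.event_size_distribution(
                    jit_units, periods, window, subsample_size=config.subsample_size,
                    n_subsample_repeats=config.n_subsample_repeats, rng=rng,
                )
                dev = ev.deviation_index(obs, jit)
                for k in sorted(obs.probabilities):
                    rows.append(dict(window_ms=window, size_k=k,
                                     prob_observed=obs.probabilities[k],
                                     prob_jitter=jit.probabilities.get(k, 0.0),
                                     index=dev.get(k, np.nan)))
                thr = 0.25 if window == 20 else 0.5
                summary[f"threshold_sync_w{window}"] = ev.threshold_synchrony(
                    sus, periods, window, thr, inclusive=(window != 20),
                    subsample_size=config.subsample_size,
                    n_subsample_repeats=config.n_subsample_repeats, rng=rng,
                )
            pd.DataFrame(rows).to_csv(out / "event_sizes.tsv", sep="\t", index=False)

        if "words" in config.stages:
            _stage("words")
            seed = config.child_seed("words")
            table, means = wd.word_table(
                units, periods,
                jitter_spec=SurrogateSpec("jitter", config.jitter_halfwidth_ms, seed=seed),
                marginal_spec=SurrogateSpec("raster_marginal", seed=seed + 1,
                                            swap_multiplier=config.swap_multiplier),
                n_null_repeats=config.n_null_repeats,
            )
            table.to_csv(out / "words.tsv", sep="\t", index=False)
            summary["n_word_types"] = int(len(table))
            for kind, m in means.items():
                summary[f"mean_word_index_{kind}"] = m

        if "correlate" in config.stages:
            _stage("correlate")
            kernel = corr.build_kernel(config.rapid_sd_ms, config.slow_multiplier)
            mats = {}
            for restriction in ("total", "active_only"):
                res = corr.pairwise_correlations(units, kernel, periods, restriction)
                mats[restriction] = res
                res.to_frame().to_csv(out / f"correlations_{restriction}.tsv", sep="\t")
                summary[f"mean_corr_{restriction}"] = res.mean_correlation
            sweep = pd.concat(
                [
                    corr.window_sweep(units, periods, config.sweep_rapid_ms, r)
                    for r in ("total", "active_only")
                ]
            )
            sweep.to_csv(out / "window_sweep.tsv", sep="\t", index=False)
            summary["n_limited_mean_corr"] = corr.n_limited_mean(
                units, kernel, periods, "total", n=config.subsample_size,
                repeats=config.n_subsample_repeats,
                rng=np.random.default_rng(config.child_seed("correlate")),
            )

        if "couple" in config.stages:
            _stage("couple")
            seed = config.child_seed("couple")
            results = []
            for group in ("L2_4", "L5_6"):
                members = [u for u in units if u.layer_group == group]
                if len(single_units(members)) < 1 or len(members) < 2:
                    continue
                results.append(
                    cpl.normalized_coupling(
                        units, group,
                        SurrogateSpec("raster_marginal", seed=seed,
                                      swap_multiplier=config.swap_multiplier),
                        n_surrogates=config.n_null_repeats,
                        lag_ms=config.coupling_lag_ms,
                        smooth_sd=config.pop_smooth_sd_ms,
                    )
                )
            if results:
                frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
                if rates is None:
                    rates = rate_summary(units, periods)
                frame = frame.merge(
                    rates[["unit_id", "total_rate_hz", "n_spikes"]], on="unit_id"
                )
                frame.to_csv(out / "coupling.tsv", sep="\t", index=False)
                summary["mean_coupling"] = float(frame["coupling"].mean())
                r, p = cpl.coupling_rate_relation(results, rates)
                summary["coupling_rate_r"] = r
                summary["coupling_rate_p"] = p
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = dict(
        source=source,
        config=asdict(config),
        stage_seeds={s: RunConfig.child_seed(config, s) for s in _STAGES},
        numpy_version=np.__version__,
        elapsed_s=round(time.time() - t0, 2),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
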