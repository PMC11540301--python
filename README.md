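# axonav

Analysis pipeline for single-axon two-photon calcium imaging recorded while
head-fixed mice navigate virtual-reality linear tracks: trace quality
control, behavioral alignment, tuning-curve construction, regression-based
encoding classification, population resampling comparisons, and
shuffle-bootstrap detection of novelty responses — plus a synthetic-data
generator with known ground truth so every stage is testable without
experimental data.

## What's in the box

| module              | purpose                                                                 |
|---------------------|-------------------------------------------------------------------------|
| `axonav.session`    | session data model + documented CSV/JSON on-disk format (round-trip exact) |
| `axonav.simulate`   | synthetic cohorts: run/pause locomotion, reward→pause→teleport laps, familiar→novel switch, GCaMP-kernel rendering, bleb controls, "unhealthy" step axons |
| `axonav.behavior`   | Savitzky–Golay velocity, lap segmentation, freezing ratio, motion-onset events, running/immobile frame filters |
| `axonav.trace_qc`   | rolling-percentile ΔF/F (300/2000-frame windows), correlated-ROI merging (r ≥ 0.7), spectral SNR filter against bleb controls (mean + 1.5 sd), CUSUM sustained-shift exclusion, quantile/mean normalization |
| `axonav.tuning`     | position (5 cm), velocity (1 cm/s, 1–30), distance/time-to-reward curves; motion-onset and environment-switch aligned matrices; lap and 50-frame binning |
| `axonav.inference`  | OLS + F tests, per-ROI encoding classification, 1000× down-sampled regression clouds, ANCOVA/ANOVA with Tukey HSD, shuffle-bootstrap 95% null bands, significant-run detection |
| `axonav.pipeline`   | end-to-end orchestration with a single config + seed, deterministic CSV/JSON/markdown outputs |

## CLI

```sh
axonav run --out out/            # full chain on the packaged demo config
axonav run --config cfg.yaml --out out/ --seed 3

axonav simulate --out sims/      # write synthetic sessions + ground truth
axonav qc --in sims/ --out qc/
axonav tuning --in sims/ --out curves/
axonav align --in sims/ --out aligned/
axonav novelty --in sims/ --out nov/
axonav stats --in sims/ --out stats/
axonav report --out out/         # re-render report.md from a finished run
```

`run` writes `qc_report.csv`, `lap_summaries.csv`, `tuning_curves.csv`,
`regression_fits.csv`, `classifications.csv`, `novelty_aligned.csv`,
`novelty_runs.csv`, `group_comparisons.csv`, `manifest.json` (config +
hash + seed) and `report.md` with figures. Re-running the same config
reproduces every text output byte-for-byte.

A pipeline config is YAML/JSON mirroring `axonav.pipeline.PipelineConfig`;
set `input_dir` to analyze sessions on disk or `sim` (a
`axonav.simulate.SimConfig` mapping) to generate them.

## Session directory format

```
session/
  behavior.csv   # frame, position_cm, reward, teleport, env_label, valid
  traces.csv     # frame + one raw-F column per ROI
  derived.csv    # optional: <roi>:<dff_short|dff_long|norm_q|norm_mean>
  rois.json      # per-ROI kind (axon|bleb) and merge provenance
  session.json   # frame rate, track length, env schedule, metadata
```

Frames are 0-based, intervals half-open, floats written with 17 significant
digits so sessions round-trip bit-exactly.
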