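# detect-ecg

A data-improvement pipeline for **biometric identification from single-lead
ECG**. Everyone's heartbeat traces the same P-QRS-T cycle, but the
amplitudes and timings of those waves are individual enough to identify a
person. This package implements the full chain from raw signal to identity
decision, and — its actual point — quantifies how much each *data-quality*
step improves identification:

1. **Filtering** — 4th-order Butterworth band-pass, 1–40 Hz (baseline wander
   lives below ~0.5 Hz, muscle/power-line artifact above 40 Hz).
2. **Blind segmentation** — fixed 3-s windows, no beat localisation; one
   minute of signal yields 20 segments.
3. **Window augmentation** — additional randomly-positioned 3-s windows
   (default 80 per subject).
4. **Fiducial features** — an R-peak detector (local maxima ≥ 66% of the
   per-window maximum) anchors Q, S, QRS onset/offset (maximum-slope search
   in a 40-ms window), P and T; each segment becomes a 22-slot feature
   vector (Q/R/S amplitude statistics, QRS amplitude, R-wave duration, R-R
   interval, P/T amplitudes, and inter-wave intervals).
5. **IQR outlier removal** — per-feature-column limits; any out-of-limits
   value discards the row.
6. **Identification** — one-vs-rest random forests (one binary forest per
   enrolled subject); a probe goes to the forest with the highest
   positive-class probability.
7. **Evaluation** — per-subject FAR = FP/(FP+TN), FRR = FN/(TP+FN),
   precision, recall, F1, with macro mean ± sd summaries and a precision
   histogram.

Four canonical configurations are compared: **scenario1** (blind windows,
9 QRS features), **scenario2** (+augmentation), **scenario3** (+outlier
removal) and **detect** (+the full 22-feature set).

Because the population-scale sleep-laboratory recordings the method was
designed for cannot ship with a package, a first-class **synthetic cohort
generator** (`detect_ecg.synthcohort`) produces multi-subject single-lead
ECG with per-subject sum-of-Gaussians P-QRS-T morphology, heart-rate
variability, configurable noise, and exact per-beat ground-truth wave
positions — so the detector and feature extractor are tested against known
truth. See `docs/methods.md` for the model and its limits.

## Worked example

```
$ detect synth --subjects 20 --duration 60 --seed 7 --noise moderate cohort/
wrote 20 recordings; manifest: cohort/manifest.json
$ detect run --scenario all --cohort cohort/manifest.json --seed 7 --out results/
scenario1: macro precision 0.9158, FAR 0.004605, FRR 0.087500
scenario2: macro precision 1.0000, FAR 0.000000, FRR 0.000000
scenario3: macro precision 1.0000, FAR 0.000000, FRR 0.000000
detect: macro precision 1.0000, FAR 0.000000, FRR 0.000000
```

With only the 20 blind windows per subject and nine QRS-complex features
(scenario1), 8.75% of genuine test windows are rejected and macro precision
sits at 92%; the improvement steps lift this 20-subject cohort to errorless
identification — augmentation quadruples the training windows, outlier
removal drops extreme feature rows, and the full 22-feature set adds the
P/T-wave information. `results/` holds one JSON report per scenario (per-subject
confusion counts and metrics, macro summaries, precision histogram, stage
counts, config hash) plus `comparison.csv`. Larger, noisier cohorts
separate the scenarios further; re-running with the same seed reproduces
every byte.

The same stages are available as a library:

```python
import detect_ecg as d

cohort = d.sample_cohort(n_subjects=20, duration=60, fs=200, seed=11,
                         noise=d.MODERATE_NOISE)
reports = d.run_all_scenarios([rec for rec, _ in cohort], seed=11)
print(reports["detect"]["macro"]["precision_mean"])
```

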