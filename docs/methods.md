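# Methods

This package implements a *data-improvement* pipeline for biometric
identification from single-lead ECG, together with a synthetic-cohort
generator that makes every stage testable against analytic ground truth.
The question the pipeline answers is not "which classifier is best" but
"how much does each data-quality step — window augmentation, outlier
removal, extra fiducial features — improve closed-set identification".

## Signal model and synthetic cohorts

Each subject is modelled as a sum-of-Gaussians beat template: five bumps
(P, Q, R, S, T) with per-subject amplitudes `a_w` (mV), widths `σ_w` (s) and
offsets `μ_w` (s) relative to the R apex, repeated at R-apex times generated
by a jittered heart-rate process,

    x(t) = Σ_beats Σ_w a_w · exp(−(t − t_R − μ_w)² / 2σ_w²) + noise(t).

Per-subject parameters are drawn once per cohort from uniform ranges around
textbook lead-II values (R ∈ [0.8, 1.6] mV, Q ∈ [−0.20, −0.05] mV,
S ∈ [−0.35, −0.10] mV, P ∈ [0.10, 0.25] mV, T ∈ [0.20, 0.45] mV; mean heart
rate ∈ [55, 90] bpm). The inter-subject spread of these draws is the entire
source of identifiability — the features the extractor measures are exactly
the quantities that differ. Per-beat jitter (rate sd 1.5 bpm truncated to
the physiological 40–208 bpm range, 2% multiplicative amplitude jitter)
provides within-subject variability.

Noise is additive: a baseline-wander sinusoid below 0.5 Hz, a power-line
sinusoid at 50 Hz, and white broadband noise. The "moderate" level used in
the scenario experiments is 0.10 / 0.05 / 0.08 mV respectively. The ground
truth records the *analytic* wave positions (rounded to samples), not
post-noise argmaxes, so exact-recovery assertions use zero-noise cohorts.

What this generator does **not** emulate: transient acquisition artifacts
(electrode motion, detachment), pathological rhythms, U waves, respiratory
and autonomic heart-rate structure, multi-lead geometry, or long-term
morphology drift. Two consequences matter for interpreting results. First,
passing tests show the pipeline's *mechanics* are correct, not that real
populations of thousands are separable at the reported rates. Second, with
purely stationary noise the feature table contains few genuinely abnormal
rows, so the outlier-removal stage has little to work with (see "Scenario
ordering" below).

All randomness derives from one run seed through SHA-256 of
`(seed, stage-tag, subject-id)`, so any stage can be re-run in isolation and
per-subject draws do not depend on cohort ordering.

## Filtering

A fourth-order Butterworth band-pass, 1–40 Hz, designed in second-order
sections. Default application is zero-phase (forward–backward via
`sosfiltfilt`, with scipy's default odd-reflection padding): this squares
the magnitude response but introduces no group delay, and fiducial *timing*
is the pipeline's core signal. A causal single-pass mode exists for fidelity
experiments. The 1 Hz cutoff (not the 0.5 Hz baseline-wander bound) is the
normative low edge.

## Segmentation and augmentation

Only the first 60 s of each recording are used. Blind segmentation cuts
non-overlapping 3-s windows from offset 0 (20 per minute at 200 Hz),
discarding a trailing partial window. Augmentation draws window start
offsets uniformly with replacement over `[0, len − window]` — windows may
overlap, and the 80 augmented windows are pure random draws, independent of
the blind grid. Because overlapping windows from one recording end up on
both sides of the train/test split, augmented scenarios measure
re-identification of *the same recording session*, which is also what the
original study's protocol measures.

## Fiducial detection

Per 3-s segment:

1. **R**: strict interior local maxima at or above 66% of the segment
   maximum; peaks closer than `min_rr_s` (0.25 s, the period at the 208 bpm
   ceiling) are merged keeping the larger. Setting `min_rr_s = 0` restores
   the literal published recipe.
2. **Q/S**: first local extremum scanning backward/forward from R within a
   0.1-s window. The published recipe says "first local maximum", but Q and
   S are physiologically troughs and the recipe's own figure shows troughs;
   the default accepts either polarity (`qs_mode="extremum"`), with a
   literal strict-maximum mode behind `qs_mode="maximum"`.
3. **QRS onset/offset**: within a 40-ms window walking away from Q (resp. S),
   the sample maximizing the chord slope `|x[q] − x[t]| / |q − t|`. Slope
   ties resolve to the window's far edge on both sides.
4. **P/T**: the local extremum with the largest absolute deviation from the
   window median, searched 0.2 s before the onset and 0.4 s after the offset
   (window lengths are not specified by the recipe; these are standard
   PQ/QT interval scales and are configurable). A candidate deviating less
   than 0.02 mV from the window median is treated as absent — without this
   floor, a P-less beat yields "extrema" of ~1e−9 mV where Gaussian tails
   cross. A clipped search window also yields an absent wave.

Beats failing any sub-locator are dropped; a segment with no surviving beat
is rejected. On zero-noise cohorts the detector recovers ≥99% of R apices
within ±2 samples and ~100% of Q/S/P/T within ±3 samples wherever the
search window fits inside the segment.

## Features

22 per-segment slots, aggregated over annotated beats: means and population
standard deviations of Q/R/S amplitudes (6), QRS amplitude (mean R − S),
R-wave duration (mean t_S − t_Q), R-R interval (needs ≥2 beats), mean P and
T amplitudes, QS and QT amplitude distances (Q − S, Q − T in mV), QRS
onset/offset amplitudes, QT and ST intervals (T apex minus Q resp. S),
T-wave duration, PQ/ST/TP segments and the P-P interval. Durations are in
ms (`1000/fs` per sample), amplitudes in mV.

Slots without published formulas are declared interpretations, one function
each so alternates can be swapped: the T-wave duration is twice the interval
from the T apex back to its half-height crossing (no T-onset/offset detector
exists in the recipe), the ST segment runs from QRS offset to that crossing,
and the QS/QT "distances" are amplitude differences — they are listed among
the amplitude features, and a timing reading would duplicate the R-wave
duration and QT interval exactly.

The *base* set (first 9 slots, QRS-only) is what scenarios 1–3 use; the
*full* 22-slot set is the DETECT configuration. A segment that cannot fill
every required slot of its scenario's set (or fills a duration slot with a
negative value) is rejected rather than imputed.

## Outlier removal

Per feature column, rows strictly outside the column's limits are dropped;
a row is removed if any column flags it. Two readings of the published
"0.5% limits" rule are implemented:

* **Tukey fences** `[Q1 − 0.5·IQR, Q3 + 0.5·IQR]` (the `OutlierSpec`
  default, m configurable, linear-interpolation quartiles).
* **Quantile cut** at the 0.5th/99.5th percentiles.

The scenario runner uses the quantile reading. The fence reading with
m = 0.5, fitted on the pooled multi-subject table, is far too aggressive at
cohort scale: the pooled column distributions are mixtures across subjects,
their IQR spans the subject spread, and subjects at the morphological tails
lose *every* row — which eliminates whole identities and makes the outlier
scenarios unrunnable. The quantile cut removes only extreme rows (~1% per
column), matches the "%" phrasing of the rule, and keeps every subject
enrolled. Fences are fitted on the whole table before the train/test split,
reproducing the published stage order; fitting on the training rows only
(`fit_scope="train_only"`) is available to avoid the mild leakage this
implies.

## Identification and evaluation

One-vs-rest with one `RandomForestClassifier` per enrolled subject
(positives = that subject's rows, negatives = everyone else's; no
subsampling or class weights). Defaults are the original grid-search
optimum: `max_depth=100, min_samples_leaf=3, min_samples_split=10,
n_estimators=120`; the 3×3×3×3 grid is available via `grid_search`
(3-fold stratified CV, ties to fewer trees then shallower depth). A probe
is assigned to the subject whose forest emits the largest positive-class
vote fraction; exact ties go to the lexicographically first label
(closed set — every probe maps to an enrolled subject). Training rows are
canonically sorted before fitting so that permuting the input table cannot
change the seeded model.

The split is per-subject stratified, 80/20 by default, seeded. Evaluation
re-reads the multi-class predictions as per-subject accept/reject decisions:
FAR = FP/(FP+TN), FRR = FN/(TP+FN), precision, recall, F1. Ratios with zero
denominators are reported absent and excluded from macro means rather than
coerced to 0. Macro summaries are per-subject mean ± sample sd; micro
(pooled-count) aggregates are also emitted, and micro recall equals plain
accuracy by construction. The precision histogram uses bins ≤60%, 60–70,
70–80, 80–90, 90–100%.

## Scenarios and scenario ordering

| scenario  | segmentation | outlier removal | features |
|-----------|--------------|-----------------|----------|
| scenario1 | blind, 20    | off             | base 9   |
| scenario2 | random, 80   | off             | base 9   |
| scenario3 | random, 80   | on              | base 9   |
| detect    | random, 80   | on              | full 22  |

On 50-subject moderate-noise cohorts (10 seeded replicates, 30-tree forests
to fit a single CPU), augmentation (1→2) and the extra features (3→detect)
improve macro precision in every replicate, and DETECT is the best scenario
in every replicate. The outlier step (2→3) is a consistent slight
*regression* (~0.2–1 pp) here: with stationary synthetic noise there are
almost no corrupted rows to remove, so the step only shrinks the data. This
mirrors the original study's own observation that scenario 3's FAR was
slightly worse than scenario 2's; in real recordings the step targets
acquisition artifacts (electrode motion, detachment) that this generator
deliberately does not simulate. The full monotone chain 1→2→3→detect is
therefore *not* reproduced on synthetic cohorts, and the corresponding
acceptance test documents this as a failing expectation rather than
weakening the condition.

## Problem sizes and numerical choices

The default experiments use 60-s recordings at 200 Hz; the scenario
comparison uses 20 subjects with the full 120-tree configuration
(`scripts/acceptance.py`) and 50 subjects with 30-tree forests for the
replicated ordering experiment; fiducial validation uses 10 zero-noise
subjects (~700 beats). Quartiles use linear interpolation (small-n quartiles
differ across conventions); sample indexing is 0-based with half-open
windows everywhere; report JSON is serialized with sorted keys and
round-trip float repr so equal runs are byte-identical.

## Known limitations

* Synthetic separability is optimistic: ~20 well-spread morphologies are far
  easier than ~2000 real subjects, so absolute metric levels here should not
  be compared with published population-scale numbers.
* Window augmentation before splitting leaks session information between
  train and test; this is the published protocol, but the numbers measure
  session re-identification, not enrolment-to-probe generalisation.
* The WFDB reader supports single-`.dat`, format-16 records only.
* No open-set operation: every probe is assigned to some enrolled subject.
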