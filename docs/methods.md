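# Methods

This note records the models, conventions, and design choices behind the
package, in the order the pipeline runs them.

## Synthetic study conditions

No public corpus pairs month-long ambient + wearable streams with clinical
scores, so the package generates its own cohort from an explicit model. The
generator's defaults are the study conditions every test runs under.

**Routines.** Each participant has a block schedule (sleep, morning hygiene,
cooking, meals, office work on weekdays, chores on weekends, exercise,
evening entertainment, and one or two out-of-home errand trips). Block start
times get Gaussian jitter (1.5–25 min s.d. depending on the block) and
durations Gaussian noise; blocks are painted onto a per-minute canvas in
schedule order, so later-listed blocks (night bathroom visits, trips)
interrupt earlier ones, and uncovered time is an at-home "relax" filler. Per
participant: wake hour ~ N(6.5, 0.75) h, sleep hour ~ N(22.5, 0.75) h,
circadian amplitude ~ U(0.4, 0.9), movement intensity ~ U(0.7, 1.3), 1–2
trips/day. Activity base rates in real cohorts are unknown; these defaults
are the package's own choice of a plausible older-adult day and are not
calibrated to any dataset.

**Ambient events.** Motion firings (ON/OFF pairs) cluster in the active
block's region at a mean interval of clip(12 / intensity, 20, 600) s; cooking
adds stove-temperature readings and a cabinet-door pair; hygiene toggles the
bathroom light; leaving/entering home fires the entry door. Background noise
firings (mean interval 1 h while home) make windows non-separable on purpose.
Roughly two sensor units per region are emulated via unit-index suffixes.

**Watch stream.** 1 Hz. Acceleration is a 1 g vertical gravity baseline plus
Gaussian noise whose s.d. is (activity intensity) x (participant movement
intensity) x (1 + 0.25 · amplitude · cos(2π(h − 14)/24)); rotation noise
scales analogously with a per-activity gyroscope factor; speed and location
type follow the block (road ≈ 8 m/s for vehicle travel, ≈ 0.9 m/s for
errands on foot). Gravity is fixed on one axis — orientation dynamics are not
modeled, which keeps magnitudes realistic without a full IMU model.

**Gaps.** Per day, total gap minutes ~ max(0, N(5.59, 5.33)), split into one
or two non-overlapping contiguous spans at uniform positions. Truncation at
zero lifts the realized mean slightly above 5.59; removed-sample counts equal
drawn span lengths exactly.

**Scores.** Each of the 7 target scores is 0.5 + Σ w·z(parameter) + N(0,
score_noise_sd), clipped to [0, 1], where z standardizes routine parameters
at their population scale. Supplemental scores (default 20, round-robin over
targets) are 0.5 + 0.15(ρ·z_target + √(1−ρ²)·ε) with ρ = score_correlation
(default 0.8), so the joint stage has exploitable structure. Demographics are
a small numeric vector (age ~ N(69, 10.9), gender, education, race category,
preexisting-condition count).

**What the generator does not emulate:** multi-resident homes, sensor
dropout/physics, real GPS geometry, orientation change, non-stationary
routines, or realistic score distributions. Passing tests therefore show the
pipeline recovers structure *of the kind assumed*, not that it matches any
real cohort's effect sizes.

## Activity recognition

Ambient windows are the 30 most recent events (stride 1; stream starts
left-padded by replicating the first event, so every reading gets a label,
attached to the window's final event). Watch windows are non-overlapping 5 s
blocks; each sample inherits its window's label; window ground truth is the
modal sample label. IMU channels are low-pass filtered (zero-phase
Butterworth, order 4, 0.3 Hz cutoff at 1 Hz sampling) per contiguous segment
before feature extraction.

Degenerate-statistic conventions (all map to 0): autocorrelation, skewness,
kurtosis, and coefficient of variation of a zero-variance window; direction
from the mean location at zero distance; time between peaks with fewer than
two peaks (peaks = interior local maxima above mean + 1 s.d.). Stop rate uses
a 0.5 m/s speed threshold. "Moments" are central moments of orders 2–4;
"overall trajectory" is the window's net displacement. Because the package
carries no raw coordinates, positions are dead-reckoned from speed and
heading within each day; the person's mean location, distance scale, and
top-3 location types per time-of-day bin (night/morning/afternoon/evening)
form the mobile context. The 5-point discrete Fourier transform of a window
is short — its two magnitude summaries are carried for completeness, not
spectral resolution.

Recognizers are 100-tree random forests; specialized one-class categories use
one weighted binary (in-category vs rest) forest each, with instance weights
inverse to the binary class's relative frequency. Leave-one-group-out
evaluation pools held-out predictions over folds and reports macro-averaged
precision/recall/f1 (micro-vs-macro and pooling are unstated in the
literature this follows; macro + pooled chosen). Fold training windows can be
subsampled (deterministically) to bound runtime; desk-scale tests cap folds
at a few thousand windows.

## Imputation

Missing watch seconds are filled per channel by a 100-tree random-forest
regression. Features: the k = 5 most recent observed samples of all channels
before the target second, plus the channel's same-minute-of-day value on up
to 7 prior days (minute-bin means; absent days fall back to the channel's
training mean). Training rows are a deterministic subsample of observed
seconds (default cap 1500; tests use 300–500). Filled rows keep an
`imputed` flag so marker extraction still counts them as missing readings.
With too few observations the channels are median-filled with a warning.

## Markers and the behaviorome

Ambient durations accrue each inter-reading interval to the *later* reading's
label (the reading that closes the interval); the first reading of a day
absorbs the span since midnight; time after the last reading is
unattributed. Hourly ambient durations accrue whole intervals to the closing
reading's hour (intervals are not split at hour boundaries). Watch durations
accrue 1 s per sample; total acceleration/rotation are sums of per-sample
3-vector norms (per-axis sums were rejected as orientation-dependent);
distance is Σ speed·Δt. Never-observed activities get duration 0 and
first-occurrence sentinel 86 400 s (preserves "later = larger"). Hourly
distance is carried alongside the printed hourly markers because the
regularity and circadian summaries need it.

Overall statistics per marker series: mean, median, population s.d., max,
min, zero crossings and mean crossings (strict sign changes about 0 and about
the mean — both are emitted), interquartile range, skewness and kurtosis
(standardized 3rd/4th central moments, kurtosis not excess; 0 for degenerate
series), and signal energy Σx². Hourly statistics pool all hours of all days
into one series.

**Regularity.** Hourly series are min–max scaled to [−0.5, 0.5] per
participant and metric over the whole collection period (per-day scaling
would make constant days unscalable); constant series scale to 0. RI(a,b) =
Σ_t x_t^a x_t^b / 24 is averaged over: all unordered day pairs within each
calendar (ISO) week, averaged over weeks (within-week); the same restricted
to Mon–Fri (within-weekday); and same-weekday pairs in consecutive weeks
(between-weeks). A mode with no eligible pair reports 0 with a warning. The
paper-gap choice of pair sets is the minimal faithful reading of the three
mode names.

**Circadian strength.** Spectral energy R(j) uses the mean-centered series
(without centering, a constant series leaks energy at cycle lengths that do
not divide N). The display periodogram evaluates cycle lengths 1–34 h in
0.5 h steps (j = N/c). Circadian strength is R at the 24 h cycle divided by
the total energy over the complete integer frequencies j = 1..N/2 — a
Parseval-complete denominator, so a pure 24 h tone scores ≈ 1 and white noise
scores near the reciprocal frequency count. Normalizing by the 1–34 h display
grid instead would cap a pure tone near 0.63, because off-frequency grid
points absorb leakage; the complete-frequency denominator was chosen so the
statistic is interpretable as a variance fraction.

The behaviorome concatenates the home block and watch block of: 11 statistics
per daily marker series, 11 per hourly series, 9 regularity indices (3 modes
x 3 rhythm metrics), and 3 circadian strengths per modality — 1 905 features
under the default vocabularies. The schema is a pure function of the
configuration; feature counts reported elsewhere for real deployments are not
reconstructible from printed marker lists and are not targeted.

## Two-stage inference

Scores are min–max normalized to [0, 1] with statistics from the training
fold only; test values are clipped. Regressors are sklearn
GradientBoostingRegressor(n_estimators=100, learning_rate=0.1,
loss="squared_error", max_depth=3, max_features="sqrt"). The first three
settings are the method's definition; depth and per-split column subsampling
are the package's own configuration for the ~2 000-column feature table —
sqrt-of-p sampling is standard stochastic-boosting practice
and makes the LOSO x stages x ~30 scores grid tractable on one CPU (~10x
faster per fit than exhaustive split search, with negligible accuracy change
at these sizes).

Stage one fits one regressor per score (targets and supplementals) on
demographics + behaviorome only. Stage two fits one regressor per *target*
on those features plus all other scores — ground-truth values during
training, stage-one estimates at prediction time. This train/test feature
mismatch is the method's stated design; an optional `stacked=True` mode
trains on out-of-fold stage-one predictions instead and is not the default.
Supplemental predictors are refit per modality configuration for
consistency. Degenerate correlation inputs return NaN with a warning rather
than raising, so one pathological score cannot abort an evaluation.
Correlations are computed on the normalized scale (Pearson r is invariant to
the affine rescaling).

## Desk-scale problem sizes

The package's own test and reproduction runs use: cohorts of 3–40
participants and 7–30 days; activity-recognition evaluations of 4–6
homes/subjects with 1–2 days each and fold subsampling caps of 2 500–4 000
windows; imputation trials on 2-day streams with 300–500 training rows; and
LOSO inference cohorts of n = 24–40. `scripts/acceptance.py` uses 4
homes/subjects for recognition, 6 imputation trials, and an n = 24, 14-day
cohort for the three-configuration LOSO comparison.

## Known limitations

* The joint stage does **not** reliably outperform independent prediction
  under the default synthetic conditions (supplemental-target correlation
  0.8, score noise s.d. 0.1, n = 40): measured across-target mean LOSO r
  margins hover around zero and are negative on most seeds once the
  regressors' sampling noise is properly decorrelated. Two causes: (i) the
  literal two-stage wiring trains stage two on ground-truth auxiliary scores
  but feeds it stage-one estimates at prediction time — a train/test
  distribution shift; and (ii) more fundamentally, the synthetic supplemental
  scores are functions of the noisy targets, whose noise component is
  unrecoverable from sensor features, so stage-one auxiliary estimates add
  almost no information beyond the feature matrix itself. The aligned
  (`stacked=True`) variant removes (i) but still does not win at these
  conditions. Large joint gains of the kind reported for real clinical
  batteries would require auxiliary scores that carry information beyond
  what the sensors encode.
* Under a true null (scores independent of features), leave-one-subject-out
  correlations of boosted-tree predictions are over-dispersed relative to
  the i.i.d. 2/√n band: fold-wise predictions cluster, shrinking the
  effective sample size, so ~80–93% (not ≥95%) of null |r| values fall
  within 2/√n. The distribution stays symmetric about zero — the dedicated
  leakage test confirms held-out scores influence nothing — but calibrated
  null inference would need a permutation reference rather than the normal
  band.
* Circadian *amplitude* as a generator parameter is only weakly identifiable
  from the markers, because every participant's schedule already imposes a
  strong 24 h rhythm; marker-level circadian strength is the observable the
  pipeline works with.
* One-class categories beyond those appearing in the default schedule are
  exercised with synthetic fixtures only.
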