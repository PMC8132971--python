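# behaviorome

Digital behavior markers from ambient and wearable sensing, with two-stage
joint inference of clinical health scores.

Continuous data from a sensor-instrumented home (passive infrared motion,
door, temperature, and light sensors reporting state changes) and a smartwatch
worn around the clock (1 Hz 3-axis acceleration and angular velocity, heading,
speed, location type) describe a person's daily routine in detail that no
clinic visit can. This package turns such streams into a **behaviorome** — a
fixed-length vector of digital behavior markers per person — and uses it to
predict clinical assessment scores (cognition, mobility, everyday
functioning). It is aimed at researchers in digital phenotyping and mobile
health who want a tested, end-to-end reference pipeline they can run entirely
on synthetic data.

The pipeline has five stages, each usable as a library module:

1. **Synthetic cohort generation** (`behaviorome.synthetic`) — block-schedule
   daily routines with Gaussian jitter drive both sensor modalities; watch
   gaps (mean 5.59 min/day, s.d. 5.33) emulate watch-swap transitions;
   clinical scores are noisy functions of routine parameters with correlated
   supplemental scores. Every generated reading carries its true activity
   label.
2. **Activity recognition** (`behaviorome.features`, `.recognition`) —
   100-tree random forests label each ambient reading (30-event sliding
   windows) and each watch sample (non-overlapping 5 s windows, Butterworth
   0.3 Hz low-pass before feature extraction), plus per-category one-class
   detectors with inverse-frequency instance weights. Evaluation is
   leave-one-home-out / leave-one-subject-out macro precision/recall/f1.
3. **Markers** (`behaviorome.markers`) — per day and per hour: reading
   counts, distinct activities/locations, seconds per activity and location,
   first-occurrence times; watch totals of acceleration, rotation, distance,
   and missing readings. Missing watch spans can be filled by random-forest
   imputation (`behaviorome.imputation`) using recent readings plus
   same-minute-of-day values from up to 7 prior days.
4. **Overall markers** (`behaviorome.regularity`, `.circadian`, `.assemble`)
   — summary statistics of every daily and hourly marker series, the
   regularity index

   RI(a, b) = (1/T) Σ_{t=1..T} x_t^a x_t^b,  T = 24,

   over within-week, within-weekday, and between-week day pairs of
   [-0.5, 0.5]-scaled hourly series, and circadian strength: the normalized
   periodogram energy

   R(j) = (2/N Σ_i x_i cos(2πjt_i/N))² + (2/N Σ_i x_i sin(2πjt_i/N))²

   at the 24-hour cycle. Everything is fused into one deterministic,
   schema-documented vector per participant.
5. **Joint inference** (`behaviorome.inference`) — gradient-boosted
   regression trees (100 estimators, learning rate 0.1, least squares)
   first predict every clinical score independently from demographics +
   behaviorome; a second, pseudo-independent stage predicts each target
   score again with the stage-one estimates of all *other* scores as extra
   features. Evaluation is leave-one-subject-out Pearson correlation per
   score and modality configuration (home / watch / fusion).

## Worked example

```python
import behaviorome as bv
from behaviorome.synthetic import CohortConfig

cfg = CohortConfig(n_participants=12, n_days=14, seed=3)
demo, behav, scores = bv.cohort_feature_tables(cfg)
res = bv.loso_evaluate(demo, behav, scores, configs=("fusion",), seed=3)
print(res.table.round(3))
```

prints one Pearson r per target score for the independent (`Fusion-I`) and
joint (`Fusion-J`) stages, for example:

```
         Fusion-I  Fusion-J
WTAR        0.413     0.550
TICS       -0.647    -0.490
RBANS      -0.162    -0.158
FAS        -0.359    -0.215
TUG         0.375     0.444
DEX        -0.030    -0.090
ADLC        0.297     0.716
Average    -0.016     0.108
```

Each value is the correlation between the leave-one-subject-out predictions
and the actual (normalized) scores across the 12 synthetic participants; the
`Average` row is the across-score mean. At n = 12 the per-score correlations
are very noisy (several are negative); scores whose generating routine
parameters — overall movement level, circadian structure — are well encoded
in the behaviorome (here WTAR, TUG, ADLC) fare best, and on this cohort the
joint stage lifts the average. Whether the joint stage helps on a given
cohort depends on how well stage one predicts the auxiliary scores; see
`docs/methods.md` for the distribution-shift caveat behind that. A full
command-line run of the same pipeline, including recognizer-based (rather
than ground-truth) labels:

```bash
behaviorome all --config run.yaml --out runs/demo
```

writes plain-CSV artifacts (event logs, watch streams, behaviorome table,
predictions, and a score-by-configuration correlation table) plus the
resolved configuration for exact reproducibility.

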