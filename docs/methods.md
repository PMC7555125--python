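# Methods

This note documents the models, parameter choices and numerical
conventions behind the `enose` pipeline, and what its synthetic-data
experiments do and do not demonstrate.

## Acquisition model

A record is 16 channels x 2700 samples (30 Hz x 90 s) of ADC counts.
Channels 1-14 are MOS gas sensors (MP503 ... TGS2603, in the fixed order
given in `enose.records.SENSOR_NAMES`); channels 15-16 (`SYNC_A`,
`SYNC_B`) are heater-phase square waves: a positive constant during the
3.5 s heating phase, zero during the 5.5 s cooling phase.  One thermal
period is 270 samples (105 heating + 165 cooling).  The breath sample is
injected at the heat-to-cool transition at 5000 ms (sample 150), which
places the start of the first complete heating phase at sample 45 and
lets exactly 9 complete periods fit in a record.

ADC values are stored as float64 and range-checked to the 12-bit scale
[0, 4095].  The bit depth of the original converter is not documented
anywhere we could rely on; 12 bits is the common choice for the
MEGA2560-class acquisition board involved.  Values are deliberately not
quantized to integers: the generator's closed-form identities (below)
are exact in floating point and would be destroyed by rounding, and no
downstream stage depends on integrality.

## Synthetic-cohort generator

Real study data (36 cancer / 23 control subjects) were never deposited,
so the generator emulates the *statistical structure* the pipeline
relies on:

* **Waveform.**  Each sensor's noiseless signal is a pure function of
  heater phase: heating follows a rising saturation curve
  `floor + amp * (1 - exp(-t/tau_rise))`, cooling decays exponentially
  from the heating peak toward the floor with time constant `tau_cool`.
  Per-sensor (floor, amp, tau) values are package constants chosen for
  plausible variety; because all features are within-record ratios, the
  template's exact shape is immaterial as long as it is periodic and
  positive.
* **Gas response.**  From the end of the injection cooling phase
  (sample 315) the signal is multiplied by
  `exp(w(t) * (gamma_s + beta_s * effect_size * label + eps_s))`, where
  `w(t)` ramps linearly 0 to 1 over one period (chamber equilibration)
  and is 1 afterwards.  `gamma_s` (0.2-0.55) is the sensor's
  label-independent response to breath; `beta_s` is the disease
  coefficient — markedly positive (0.15-0.35) for seven sensors, near
  zero for the other seven, mimicking VOC markers visible only to some
  sensor chemistries; `eps_s ~ N(0, subject_sd)` is between-subject
  biological variability.  The cooling phase of period 1 is therefore a
  clean pre-exposure baseline and period 4 is fully equilibrated, which
  is exactly why the period-4/period-1 ratio is the response feature.
  With noise, drift and subject variability switched off, the ratio
  equals `exp(gamma_s + beta_s * effect_size * label)` exactly — the
  closed form the segmentation and feature tests pin.
* **Noise and drift.**  I.i.d. Gaussian ADC noise (default sd 8 counts)
  plus a slow multiplicative drift `(1 + 0.005)^cycle`.
* **`subject_sd` (default 0.15).**  Without between-subject response
  variability the two classes would be point masses separated by any
  nonzero effect, and every experiment would be trivially separable.
  0.15 on the log-response scale (~15 % response variability between
  people) makes the default effect size 0.5 a learnable but imperfect
  problem, which is the regime the method actually operates in.
* **Demographics.**  `demographics="study"` reproduces the published
  composition: cancer 6 F / 30 M, ages 2 in 20-40 and 34 in 40-75;
  control 16 F / 7 M, ages 14 in 20-40 and 9 in 40-50; ages uniform
  within bands (only the bands are published).  Note that under this
  composition age alone is highly predictive (no control is older
  than 50), so a cohort in `"study"` mode carries demographic signal on
  top of the sensor signal.  `demographics="balanced"` draws age and sex
  identically for both classes and exists precisely so that null-signal
  (effect 0) and signal-recovery experiments measure the sensor channel
  alone.  Smoking is Bernoulli(0.4) independent of label (no prevalence
  was published).

What the generator does **not** emulate: sensor physicochemistry
(Langmuir kinetics, humidity and temperature cross-sensitivity),
inter-sensor correlation of breath responses, chamber purge dynamics,
session-level batch effects, or any real VOC biology.  Passing tests
therefore demonstrate that the pipeline recovers class signal of the
assumed multiplicative form from records with realistic geometry and
noise — not that the classifier would achieve any particular accuracy on
clinical breath data.

## Segmentation

A heat-to-cool transition is the first index of a maximal run of zeros
on a sync channel; runs shorter than 5 samples are merged into their
neighbours (debounce) so an isolated corrupted sample cannot split a
phase.  The two sync channels must agree on every transition;
disagreement raises an error rather than voting, since acquisition
integrity is the channels' only purpose.  Indices are 0-based with
half-open intervals.  Partial first/last cycles are discarded;
`cycle_index` counts complete cycles from 1, so "period 1" downstream is
the first complete cycle — under the default timing, the injection
period.  At least 4 complete cycles are required.

## Features

`ratio = cooling_segment[period 4] / cooling_segment[period 1]`
elementwise per sensor (periods configurable), thinned to indices
0, 10, ..., 150 — the simplest convention that yields the documented 16
values per sensor; the starting offset is configurable.  A zero in the
denominator segment (ADC floor) makes the record unusable and raises.
Metadata encoding: age/100 (same order of magnitude as the ratios),
male = 1, smoker = 1.  No further normalization is applied — ratio
features are already O(1), which suits sigmoid inputs; z-scoring is a
documented possible extension, not a default.

## Network and training

227 → 454 → 1, logistic sigmoid on both layers; hidden width is fixed at
twice the input dimension.  Training is full-batch gradient descent with
hand-written backpropagation.  Unstated-in-the-field-report choices made
here: logistic cross-entropy loss by default (natural pairing with a
sigmoid output; MSE available), learning rate 0.05, Glorot-style uniform
initialization `U(+/- sqrt(6/(fan_in+fan_out)))`, evaluation every 10
epochs.  Early stopping is best-snapshot-with-patience: held-out
accuracy is recorded at each evaluation; training stops at `max_epochs`
(default 8000) or once the best accuracy is `patience` (default 200)
epochs old, never before `min_epochs` (default 500); the returned
parameters are the snapshot at the best held-out accuracy, earliest on
ties.  The 500/8000 bounds bracket the epoch window in which the
held-out error minimum is typically observed on cohorts of this size.
Decision threshold 0.5, with the tie (p = 0.5) classified positive.

Cross-entropy is computed from the output pre-activation as
`log(1 + e^z) - y z` (stable for |z| into the hundreds); a non-finite
loss raises a divergence error naming the epoch and learning rate.
Full-batch updates plus seeded initialization make training
bit-reproducible.

`TrainConfig.reduced()` (600 max epochs, min 100, patience 120) is the
short schedule used by the command-line `--profile reduced`, the heavier
tests and the acceptance script; at the default learning rate the
held-out accuracy plateau is reached well inside this window on
59-subject cohorts, and the full schedule changes the cross-validated
means only within their seed-to-seed spread.

## Cross-validation

Uniform random unstratified partitions into 5 folds, sizes differing by
at most one with larger folds first (59 → 12, 12, 12, 12, 11), redrawn
20 times: 100 experiments.  Each experiment trains on four folds with
the held-out fold as the early-stopping set and reports confusion counts
on that same fold — faithful to the original protocol and optimistic by
construction; `mode="three_way"` provides the unbiased variant.
Aggregation is the unweighted mean of per-experiment metrics (macro
average; pooled counts are also reported).  A per-experiment metric with
an empty class is recorded as missing, not zero, and excluded from the
mean.  The master seed spawns one child seed per experiment via
`numpy.random.SeedSequence`, so experiments are independent and
individually re-runnable.

## Statistical design of the null guard

With zero effect size and exchangeable demographics, a trained
classifier is label-independent, and its expected accuracy is
`p0 * P(predict 1) + (1 - p0) * P(predict 0)` for majority rate
`p0 = 36/59` — a value anywhere between the minority and majority rates,
equal to `p0` only for a degenerate always-majority predictor.  The
leakage guard therefore checks that pooled null accuracy does not exceed
`p0` by more than 1.96 binomial standard errors (the leakage direction)
and does not fall below `1 - p0` by more than the same margin (the
impossibility direction).  Demanding equality with `p0` would test a
property the estimator does not have, not the absence of leakage.

## Known limitations

* Synthetic response coefficients are placeholders; real per-sensor
  response magnitudes for breath VOCs are unpublished.
* The reported metrics inherit the single-split optimism of the original
  protocol unless `three_way` mode is used.
* The generator draws sensors' subject-level responses independently;
  real MOS arrays respond with strong inter-sensor correlation, which
  would reduce the effective number of informative channels.
* Feature extraction assumes the fixed 9 s thermal period; there is no
  period-free segmentation path, and records without intact sync
  channels are rejected.
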