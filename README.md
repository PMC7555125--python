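# enose

Breath screening for respiratory-tract cancer with an electronic nose:
a complete, tested pipeline from raw thermally cycled metal-oxide-sensor
(MOS) breath records to a cross-validated neural-network diagnostic.

## The problem and the method

Exhaled breath carries endogenous volatile organic compounds (VOCs) whose
mixture shifts with malignant disease.  An electronic nose measures that
shift with an array of partially selective gas sensors: here, 14 MOS
sensors in a sampling chamber, heaters driven in a thermal-cycling mode
(3.5 s heating, 5.5 s cooling), sampled at 30 Hz for 90 s.  Each record is
a 16 x 2700 matrix of ADC counts — 14 sensor channels plus two
synchronization channels that carry a square wave locked to the heater
phase, so the record can be cut exactly into 9-second thermal periods.
The breath sample is injected at the heat-to-cool transition at the
5000 ms mark.

The pipeline classifies subjects as follows:

1. **Segmentation** — thermal periods are located from the sync channels;
   each cooling phase is a 165-sample block (5.5 s x 30 Hz).
2. **Features** — for every sensor, the elementwise ratio of the period-4
   and period-1 cooling segments.  Period 1 is the pre-exposure baseline
   (the sample is injected at its start, before the sensors respond);
   period 4 is fully equilibrated, so the ratio is the classic e-nose
   response ratio and cancels per-sensor gain.  Each 165-value ratio trace
   is thinned to every 10th value (16 numbers per sensor); age/100, a male
   indicator and a smoker indicator are appended:
   14 x 16 + 3 = **227 input values**.
3. **Classifier** — a from-scratch one-hidden-layer perceptron
   227 → 454 → 1 (hidden width = 2 x input) with logistic sigmoid units on
   all layers, trained by full-batch backpropagation with early stopping
   on held-out accuracy.
4. **Evaluation** — repeated random 5-fold cross-validation: 59 subjects
   split into folds of 12, 12, 12, 12, 11; the partition redrawn 20
   times; 100 experiments in all, reporting mean accuracy, sensitivity
   TP/(TP+FN) and specificity TN/(TN+FP).

The study cohort (36 cancer patients, 23 controls) was never publicly
deposited, so the package ships a synthetic-cohort generator
(`enose.simulate`) that reproduces the acquisition geometry, the sync
meanders, the injection response, cohort demographics, sensor noise and
drift, with a controllable class effect size.  All results below are
computed on synthetic cohorts.

## Worked example

```python
from enose import (SynthConfig, generate_cohort, RatioFeatureExtractor,
                   TrainConfig, make_cv_plan, run_cross_validation)

cohort = generate_cohort(SynthConfig(seed=1))          # 59 records, 36 cancer
vectors = RatioFeatureExtractor().extract(cohort)      # 59 x 227 features
plan = make_cv_plan([v.record_id for v in vectors],
                    n_folds=5, n_repeats=20, seed=1)   # 100 experiments
report = run_cross_validation(vectors, plan, TrainConfig.reduced(), seed=1)
print(f"accuracy    {100 * report.accuracy:.1f}%")
print(f"sensitivity {100 * report.sensitivity:.1f}%")
print(f"specificity {100 * report.specificity:.1f}%")
```

prints, with this seed:

```
accuracy    74.3%
sensitivity 82.5%
specificity 63.0%
```

Accuracy is the fraction of held-out subjects classified correctly,
averaged over the 100 experiments; sensitivity is the detection rate
among cancer subjects, specificity among controls.  The numbers depend on
the synthetic generator's effect size (default 0.5) and between-subject
variability; they characterize the pipeline on simulated data, not any
clinical population.

The same pipeline is available from the shell:

```bash
enose run-all --workdir out/ --seed 1 --repeats 20 --profile reduced
```

(`generate`, `features` and `evaluate` also exist as separate
subcommands; exit codes: 0 ok, 2 config error, 3 validation error,
4 training divergence.)

Note on protocol fidelity: the held-out fold is used both for early
stopping and for the reported confusion counts, reproducing the original
single-split protocol; this is optimistic by construction.
`run_cross_validation(..., mode="three_way")` provides an unbiased
variant with a separate early-stopping subset.

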