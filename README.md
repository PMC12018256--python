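# tfo — transabdominal fetal pulse oximetry processing chain

`tfo` implements the signal-processing and classification chain of a
transabdominal fetal oximeter: a probe on the maternal abdomen carries two
LEDs (740 nm and 850 nm, square-wave multiplexed at 690 Hz and 940 Hz) and
five photodetectors at {1.5, 3, 4.5, 7, 10} cm from the source.  Each
detector samples a mixed photoplethysmogram (PPG) at 8000 sps containing
maternal cardiac, maternal respiratory and — orders of magnitude weaker —
fetal cardiac components.  The package turns those raw recordings into a
continuous binary detection of fetal hypoxemia, defined as instantaneous
fetal arterial oxygen saturation (fSaO₂) below 30 %.

It is written for researchers working on non-invasive fetal monitoring who
need a complete, testable reference pipeline: every stage can be exercised
against a built-in synthetic-data generator that emulates controlled
hypoxemia experiments (stepwise-declining fSaO₂, sparse arterial-blood-gas
draws, wandering fetal/maternal heart rates, motion and blood-draw
artifacts), so no animal data are required.

## Method

**Oximetry core.** The pulsatile absorbance change at wavelength λ follows
the modified Beer–Lambert law,
ΔA^λ = (S·ε_O₂Hb^λ + (1−S)·ε_RHb^λ)·ΔC_THb·⟨L⟩,
where S is arterial saturation, ΔC_THb the pulsatile total-hemoglobin
change and ⟨L⟩ the mean photon path.  The modulation ratio
Φ = ΔA^740/ΔA^850 cancels ΔC_THb and ⟨L⟩, and in practice is computed from
the AC/DC ("pulsation") ratios of the two wavelength channels:
Φ ≈ (AC^740/DC^740)/(AC^850/DC^850).  `tfo.bll` provides the forward map
S → Φ and its closed-form inverse, with a packaged 740/850 nm hemoglobin
extinction table.

**Signal chain.** `tfo.demodulate` separates the two wavelengths by
quadrature lock-in against each LED's carrier, decimates 8 kHz → 80 Hz and
converts to source-normalized received optical power.  `tfo.acdc` extracts
the DC as the lower envelope of the mixed PPG (local minima +
interpolation) and the fetal AC by lock-in detection against a
variable-frequency reference built from the fetal heart-rate trace
(φ(t) = 2π∫fhr dτ), which isolates the fetal line from much larger
maternal components.  `tfo.features` forms pulsation and modulation
ratios, rejects Φ outliers outside [0.01, 100], averages over 1.5-min
windows to 1 sample/s, and labels each second against the 30 % threshold
by linear interpolation of the blood-gas draws.

**Classification.** `tfo.fusion` is a two-head MLP: a 10 → 16
representation head consumes the pulsation ratios (standardized across
rounds) as a signature of the measurement geometry, and a
21 → 128 → 64 → 32 → 16 → 1 classification head combines it with the five
per-round-standardized modulation ratios into a hypoxemia probability.
Training uses class-weighted binary cross-entropy (weights N/(2·N_c)),
Adam (lr 1e-4, weight decay 1e-4), at most 300 epochs with patience-25
early stopping.  `tfo.crossval` implements staggered round-based five-fold
cross-validation: folds are contiguous in time, the validated fold rotates
across rounds and iterations, and training samples whose 1.5-min smoothing
windows overlap a validation window are discarded to prevent leakage.

## Worked example

Simulate a 5-minute hypoxic round (fSaO₂ stepping 50 % → 20 %), process it,
and invert the per-detector modulation ratios back to saturation:

```
$ python -c "from tfo.simulate import SimConfig; \
    SimConfig(round_duration=300, step_duration=150, sat_start=50, sat_end=20, seed=5).to_yaml('cfg.yaml')"
$ tfo simulate --config cfg.yaml --out round.h5
wrote round.h5 (300 s, 5 detectors), seed 5
$ tfo process --in round.h5 --fhr round.fhr.csv --abg round.abg.csv --out features.parquet
wrote features.parquet: 300 rows, 262 valid
```

Reading the feature table and applying the inverse ratio-of-ratios
relation per detector:

```
t=75 s    S_recovered = [42.5 42.5 42.5 42.5 42.3] %   S_true = 42.5 %   label: normoxemic
t=150 s   S_recovered = [35.0 35.0 35.0 35.0 34.3] %   S_true = 35.0 %   label: normoxemic
t=225 s   S_recovered = [27.5 27.5 27.4 27.4 27.3] %   S_true = 27.5 %   label: hypoxemic
```

i.e. the noise-free chain recovers the programmed saturation to a fraction
of a percentage point at every detector, and the label flips once the
interpolated blood-gas value crosses 30 %.

Cross-validating the fusion classifier on the built-in five-round cohort
(three rounds crossing the threshold, two entirely hypoxemic):

```
$ python -c "from tfo.simulate import simulate_feature_cohort; \
    simulate_feature_cohort(seed=0).to_parquet('cohort.parquet')"
$ tfo crossval --features cohort.parquet --out report/ --seed 0
{
  "accuracy": 0.9251,
  "sensitivity": 0.9339,
  "specificity": 0.8968,
  "precision": 0.9646,
  "f1": 0.9462,
  "auc": 0.9609
}
```

The report directory contains per-iteration metrics JSON, ROC point CSVs,
a per-iteration sample-count table and a Markdown summary.

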