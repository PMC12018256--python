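# Methods

This note documents the models, numerical choices and known limitations of
the `tfo` package, stage by stage in the order the pipeline runs.

## Oximetry model

The package works in the two-chromophore (oxy-/deoxyhemoglobin) small-signal
regime of the modified Beer–Lambert law.  The pulsatile absorbance change at
wavelength λ is ΔA^λ = (S·ε_O₂Hb^λ + (1−S)·ε_RHb^λ)·ΔC_THb·⟨L⟩ with ΔC_THb
in mM (converted internally to M) and ⟨L⟩ in cm, assumed equal at both
wavelengths.  The modulation ratio Φ = ΔA^740/ΔA^850 then depends only on S
and the extinction coefficients, and inverts in closed form:

S = (Φ·ε_RHb^850 − ε_RHb^740) / (ε_O₂Hb^740 − ε_RHb^740 − Φ·(ε_O₂Hb^850 − ε_RHb^850)).

The inverse is returned unclamped: values outside [0, 1] signal that the
measured Φ is inconsistent with a pure two-chromophore pulsation and are
left for the caller to flag, rather than silently truncated.  The packaged
extinction table (740 nm: ε_O₂Hb 446, ε_RHb 1115.88; 850 nm: ε_O₂Hb 1058,
ε_RHb 691.32 M⁻¹cm⁻¹) comes from the standard compiled hemoglobin spectra;
any user table with a non-singular extinction matrix is accepted.  With
this table Φ decreases monotonically from 1.614 (S = 0) to 0.422 (S = 1),
so rising Φ means falling saturation.  The mapping has a pole at
Φ = (ε_O₂Hb^740 − ε_RHb^740)/(ε_O₂Hb^850 − ε_RHb^850) ≈ −1.83, far outside
the physiological range; `saturation_from_phi` raises if evaluated within
tolerance of it.

## Synthetic-data generator

The generator emulates a controlled fetal-hypoxemia experiment ("round"):

- **fSaO₂ trajectory** — stepwise decline, one stage per occlusion step
  (default 600 s per stage), stage values evenly spaced from `sat_start`
  (default 60 %) to `sat_end` (default 15 %), drifting linearly within each
  stage.  Optional smooth wiggle via `sat_drift_sd` (default off).
- **Blood-gas draws** — at the 2.5, 5 and 10 min marks of each 10-min stage
  (proportionally for other stage lengths), with analyzer noise of
  sd 0.3 saturation points.
- **Heart rates** — bounded random walks (innovation sd 0.3 bpm/s,
  reflecting at the bounds): fetal 120–174 bpm, maternal 75–84 bpm.
  Respiration is fixed at 0.25 Hz (ventilator-locked) with harmonics at
  relative amplitudes (1, 0.5, 0.25) of the 0.4 % fundamental.
- **Optics** — received DC power decays exponentially with source–detector
  distance (0.8 cm⁻¹); the fraction of detected photons that traversed
  fetal tissue rises with distance (0.006 … 0.2), so the fetal pulsation
  share grows from near to far detectors while absolute power falls.  The
  fetal pulsatile amplitude relative to DC at each wavelength is
  ln(10)·ΔA^λ·fetal_fraction (the first-order expansion of 10^(−ΔA)), with
  ΔC_THb = 1 µM and ⟨L⟩ = 10 cm; this puts fetal AC/DC between 10⁻⁴ and
  4·10⁻³ — two to four orders below DC — and makes the two-wavelength
  AC/DC ratio equal Φ(fSaO₂(t)) by construction, which is what the
  end-to-end tests verify.  Maternal cardiac AC/DC is 1 %.
- **Multiplexing** — each LED's power is multiplied by a 50 %-duty on/off
  square wave (690 Hz for 740 nm, 940 Hz for 850 nm) rendered as its
  Fourier series truncated at the Nyquist frequency.  This models the
  anti-alias front end of a real acquisition chain; naively sampling an
  ideal square at 8 ksps would fold above-Nyquist harmonics into discrete
  alias lines (e.g. a ~1 % line at exactly 940 Hz from the 690 Hz carrier)
  and broadband edge-quantization jitter, both artifacts of the sampling
  model rather than of the device.
- **Artifacts** — optional baseline steps, ramps and broadband Gaussian
  bursts in specified windows, by default placed ±5 s around blood-draw
  times; samples outside the windows are bit-identical to the clean
  recording.

What the generator does **not** model: photon-transport geometry (the
fetal-fraction profile is imposed, not derived), pulse-shape harmonics of
either heart (both pulsations are sinusoids at the instantaneous rate —
sufficient because the lock-in extracts only the line at the reference
frequency), uterine contractions, fetal movement beyond slow amplitude
drift, and shared-noise correlations between detectors.  Passing tests on
synthetic data therefore demonstrate correctness of the processing chain
under the stated model, not performance on in-vivo recordings.

### Feature-level cohort

For classifier studies a faster generator maps ground-truth saturation
directly to 1 Hz feature tables, skipping the raw 8 ksps stage.  Per round
and detector it applies a log-normal sensitivity (sd 0.25 in log space,
standing in for anatomy and probe placement) to Φ(S(t)) and to the
pulsation-ratio baseline, plus multiplicative noise.  Two details matter:

- **Noise correlation.**  Every 1 Hz feature is declared to be a 1.5-min
  window mean (its `win_start`/`win_end` columns drive the cross-validation
  overlap exclusion), so feature noise is generated as white noise smoothed
  with that same window and rescaled — adjacent samples correlate exactly
  as window means do.  Independent-per-second noise would contradict the
  declared windows and make the overlap exclusion pointless.
- **Noise level.**  The default 2 % relative sd on the smoothed modulation
  ratio was calibrated against the full raw-signal pipeline: running a
  constant-saturation round through synthesis → demodulation → lock-in →
  smoothing gives per-detector smoothed-Φ scatter of 0.01–0.3 % at the
  default detector noise and 1–8 % at a hundredfold detector noise (where
  the additive noise rivals the far detector's entire signal).  2 % sits in
  the moderate-to-heavy part of that measured range.

The default cohort mirrors the animal-study composition: five rounds
(durations 20–42 min), three starting at 38–55 % saturation and crossing
the 30 % threshold, two starting below 30 % and entirely hypoxemic.

## Demodulation front end

Wavelength separation is quadrature lock-in at each carrier's fundamental:
the unipolar square's fundamental has amplitude 2/π, so the envelope is
π·√(I²+Q²) regardless of carrier phase.  The lock-in low-pass is a
zero-phase 4th-order Butterworth at 10 Hz: wide enough for the < 5 Hz
mixed-PPG band, and far enough below 30 Hz — the distance from the 940 Hz
carrier to the folded 13th harmonic of 690 Hz (8970 → 970 Hz) — to keep
cross-talk under 0.5 % even with ideal square carriers.  A 20 Hz cutoff
fails that bound (≈3 % leak); this fixed the choice.

Decimation 8 kHz → 80 Hz runs in two zero-phase FIR stages of 10
(`scipy.signal.decimate`, windowed-sinc).  An IIR (Chebyshev-I) decimator
was rejected: applied forward-backward its passband ripple squares to
~0.1 dB per stage, violating the 1 % in-band amplitude contract that the
FIR meets with margin (measured 0.25 % at 2.9 Hz).  Source normalization
divides by detector gain, LED drive current and a radiometric device
constant (default 1, config-exposed); it is exact by linearity, verified by
simulating the same scene at different gain/current settings.

## AC/DC extraction

**DC** is the lower envelope: local minima of the 3-sample-median-filtered
signal, with a minimum spacing of a quarter maternal cardiac period
(estimate 1.3 Hz, config-exposed) to skip noise dimples, linearly
interpolated onto the 80 Hz grid and extended by the nearest minimum at the
edges.  Fewer than two minima (monotone input) falls back to a constant
global minimum with a flag.  The envelope sits ≈1 % below the true DC under
the default 1 % maternal pulsation — an inherent property of lower-envelope
DC estimation.  The bias is common to both wavelengths and cancels in Φ.

**AC** is quadrature lock-in against a unit reference at the instantaneous
fetal heart rate, φ(t) = 2π∫fhr dτ (trapezoid integration of the linearly
interpolated reference trace; traces with gaps beyond 10 s are rejected
with the gap location).  The output 2·√(I²+Q²) restores the amplitude of an
on-reference sinusoid and is invariant to its phase.  The low-pass is a
zero-phase 4th-order Butterworth at 0.15 Hz (config-exposed): it must
reject the maternal line, which stays ≥ 0.6 Hz from the fetal rate in the
modeled regime, while following the slow drift of the fetal amplitude.
Before mixing, the signal is high-passed at 0.5 Hz (zero-phase, 4th
order): the quasi-static baseline is 10²–10⁴ times the fetal amplitude,
and its energy leaks into the AC estimate through the spectral wings of
the frequency-wandering reference unless removed.  Subtracting the lower
envelope instead was tried and rejected — the envelope's kinks at the
minima inject maternal harmonics directly into the fetal band.

The FHR reference is taken from ground truth (in an experiment, from a
carotid arterial line); estimating FHR from the PPG itself is out of scope.

## Features and labels

Pulsation ratios are pointwise AC/DC (invalid where DC ≤ 0, flagged rather
than raised).  The pointwise modulation ratio Φ = pr₇₄₀/pr₈₅₀ is screened
against [0.01, 100] — values outside mean the two wavelengths disagree by
more than two orders of magnitude, i.e. a corrupted measurement — and the
survivors are averaged in centered 90 s windows to 1 sample/s, a window
needing at least 10 contributing points (config-exposed) to be valid.
Pulsation features are window means over the same centered window, so a
row's 15 features describe the same stretch of raw data, recorded in the
row's `win_start`/`win_end`.  A centered window keeps features time-aligned
with labels.  Labels come from linear interpolation of the blood-gas
draws; a sample is hypoxemic iff the interpolated value is strictly below
30 % (a draw at exactly 30 % is normoxemic), and samples outside the draw
span are invalid.  A row is valid iff all 15 features and its label are.

## Fusion classifier

Architecture: representation head 10 → 16 (ReLU), classification head
concat(16 + 5) = 21 → 128 → 64 → 32 → 16 → 1 with ReLU after each hidden
layer and a sigmoid output; fusion is by concatenation (the minimal
combiner).  Pulsation ratios are standardized across rounds — fitted on
training samples only by default, since fitting on validation data would
leak; a flag allows fitting on all samples.  Modulation ratios are
standardized per round on each round's own samples: this is within-round
normalization (the round's scale is subject anatomy, not outcome
information), accepted as such.

Training: class-weighted BCE with weights N/(2·N_c); Adam with lr 1e-4 and
L2-coupled weight decay 1e-4; mini-batches of 64 (full-batch training
would give only 300 optimizer steps at this learning rate — far too few);
at most 300 epochs with early stopping after 25 epochs without validation
improvement, restoring the best checkpoint.  The stopping criterion is the
validation BCE computed with the same class weights as training: an
unweighted criterion systematically prefers majority-class-calibrated
checkpoints and can erase the recall benefit the weighting exists to
provide.  Weights are initialized from a normal distribution scaled per
layer as √(2/fan_in) (He scaling); a fixed small std (e.g. 0.01) makes
activations and gradients vanish multiplicatively through the five layers
and the network cannot train within the fixed epoch budget.  Biases start
at zero.  All randomness (init, shuffling) flows from explicit seeds; two
runs with the same seed produce identical histories.

The model is implemented directly on NumPy (a few small dense layers);
this keeps initialization, the optimizer update and the training loop
exactly reproducible and dependency-light.

## Cross-validation and metrics

Each round's valid samples, time-sorted, are cut into five contiguous
folds with boundaries floor(k·l/5); remainder samples land in the last
fold.  Round r (in round order) validates the fold starting at fraction
0.2·((r + j) mod 5) in iteration j, so every sample is validated exactly
once across the five iterations and the validated region rotates through
each round's saturation trajectory.  Before training, any training sample
whose smoothing window has positive-measure overlap with a validation
sample's window is discarded (touching endpoints do not count); with 90 s
centered windows this removes ±90 s around each validation block.

Each iteration trains on the pooled training samples of all rounds and is
evaluated on the pooled validation samples: confusion-matrix metrics at
threshold 0.5 (hypoxemia positive), ROC over unique probabilities,
trapezoid AUC, and a stratified-bootstrap percentile CI for the AUC
(default 1000 resamples in the library, fewer in tests for speed; the CI
method is this package's choice).  Single-class validation pools report
the undefined rates as NaN with a warning, and the five-iteration summary
is the NaN-aware mean.

## Problem sizes used in tests

The test suite and acceptance script scale the study down to keep the
checks sharp and the signals fully verifiable: the shared noise-free round
is 240 s with 120 s stages; the end-to-end saturation-recovery round is
600 s with 150 s stages (60 % → 15 %, four midpoints × five detectors
checked to ±2 saturation points, measured worst error ≈ 0.05 points); the
classifier cohort uses the five default rounds (≈ 8000 one-second samples)
with cross-validation repeated at seeds 0–2.  Stage durations only set how
long saturation dwells at each level; none of the verified properties
depend on them.

## Known limitations

- The extinction table is for adult hemoglobin; fetal hemoglobin is
  spectrally similar in this window but not identical.
- The DC lower envelope is biased low by the maternal pulsation amplitude;
  pulsation ratios inherit a bias of the same relative size (≈1 % at
  defaults).  Φ and everything downstream are unaffected.
- Lock-in AC extraction assumes the maternal and fetal cardiac lines stay
  separated by well over the 0.15 Hz filter band; crossing rates (not
  observed in the modeled regime) would corrupt the fetal amplitude.
- The classifier's per-round modulation standardization requires each
  round's samples at inference time; the model is a within-round detector,
  not a calibration-free absolute oximeter.
- Cross-validation needs rounds long enough that a validation fold plus
  the ±90 s exclusion zone leaves training samples of both classes;
  rounds of only a few minutes fail this structurally.
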