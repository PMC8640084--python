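# Methods

`impactkit` implements an impact-classification pipeline for an
instrumented mouthguard: three triaxial linear accelerometers (nominally
3,200 Hz, ±200 g, 12-bit) and a triaxial gyroscope (nominally 800 Hz,
±2,000 dps, 16-bit) record threshold-triggered *captures*, which are
triaged, featurised and classified as *hit* (video-verifiable contact with
another player, the ball or the ground) or *non-hit* (chewing, yelling,
mouthguard handling, ...).  The real match data behind this design are
proprietary, so the package includes a synthetic capture simulator that
reproduces the statistical structure every stage relies on; all validation
is performed on that synthetic corpus.

## Capture model

A capture holds four sensor streams, trigger metadata and a review label.
Samples are stored in physical units (g, dps) — quantisation to the ADC
grid (step = range / 2^(bits−1)) is applied only inside the simulator.
`trigger_index` is 0-based on the left accelerometer at its actual rate,
because the onboard trigger thresholds that sensor's Euclidean norm.
Sessions are stored as self-describing JSON (`*.captures.json`) with a
header (devices, calibration matrices, label vocabulary) and per-capture
columnar sample blocks; floats round-trip exactly via `repr`.

## Trigger and triage

* **Onboard trigger** — raw left-accelerometer norm ≥ 10 g.  A capture
  spans 20 ms before the first crossing to 80 ms after the last; crossings
  closer than the 80 ms tail merge into one capture.  Windows at stream
  edges are clipped, not discarded.
* **Triage** — the norm is low-pass filtered at 300 Hz with a second-order
  Butterworth filter applied in a single causal pass ("non-phase
  corrected" = not forward–backward), then re-thresholded at 10 g.  This
  removes vocalisation and other high-frequency-only captures.  The
  trigger uses the raw norm, triage the filtered norm.

A subtlety worth knowing: the norm of a narrowband signal is rectified, so
it carries a DC component of about 2/π times its envelope.  A vocalisation
must therefore stay below ~15.7 g peak for the filtered norm to remain
under 10 g; the simulator's yelling class respects this.

## Resampling

All channels are brought to a common 3,200 Hz before feature extraction.
The rate ratio is approximated by a rational number (denominator ≤ 1,000)
and applied with `scipy.signal.resample_poly` (Kaiser-windowed polyphase
filter).  Streams already at 3,200 Hz pass through untouched.  The
upsampled gyroscope has no physical content above its original 400 Hz
Nyquist; residual spectral images of strong pulses do appear above 400 Hz
at the filter's stop-band level and are monotone in source power (see the
simulator notes below).

## Features

Twelve aligned signals (3 accelerometers × 3 axes + 3 gyro axes) feed two
families:

* **Random convolutional kernels** (ROCKET-style): length ∈ {7, 9, 11},
  N(0,1) weights mean-centred, bias ~ U[−1, 1], dyadic dilation bounded so
  the receptive field fits a 320-sample capture, padding ~ Bernoulli(0.5).
  Each signal is z-scored to its own mean/SD, then per kernel the maximum
  of the convolution output and the proportion of positive values (ppv)
  are emitted.  One shared kernel set is applied to every signal; the
  reference configuration uses 300 kernels → 600 features per signal.
  Signals shorter than a kernel's receptive field (possible for
  edge-clipped captures) are zero-extended rather than rejected.
* **Binned log Welch PSD**: Hann window, 256-sample segments, 50 %
  overlap, FFT zero-padded to 512 points.  The zero-padding matters: at
  12.5 Hz native resolution roughly one in five 10-Hz bins would contain
  no frequency at all; the 6.25 Hz interpolated grid populates every bin.
  Bin *characteristic value* = mean PSD of the frequencies inside the bin
  (scale-stable under bin occupancy); bins span (10 Hz, 1,600 Hz]
  labelled by lower edge — the DC bin is excluded — giving 159 values per
  signal, 1,908 over 12 signals.  Natural log with a 1e−30 floor.

All features are standardised to the training subset's mean and
*population* SD (ddof = 0); zero-SD columns map to zero under an epsilon
guard.

## Dataset construction

Captures from one designated session form the holdout set and never touch
training or selection.  The remainder (Set 1) is balanced by uniformly
downsampling non-hits to the hit count, then split per class into 70 %
train / 15 % validation / 15 % test (train takes the floor; an odd
remainder index goes to validation).  Non-hits excluded by balancing form
the *rest* set, which probes specificity under the natural ~10:1
imbalance.  On the reference corpus counts (1,580/11,837 plus a 57/238
holdout) this yields a 3,160-capture balanced set with 1,106 training hits
and a 10,257-capture rest set.

## Classifier selection and tuning

A roster of untuned classifiers is fitted on the training subset and
scored on validation TP% (hits recovered) and TN% (non-hits recovered).
The selection rule — stated as an intent in the literature this design
follows — is formalised as: maximise mean(TP%, TN%), break ties by the
smaller |TP% − TN%|, then by roster order.  The default roster is a
compact, fast subset of scikit-learn classifiers plus
`HistGradientBoostingClassifier` and XGBoost; a fuller roster is available
(`default_roster(compact=False)`) since library inventories drift.

The gradient-boosted ensemble (XGBoost) is then tuned by randomized
search: 50 candidates × stratified 5-fold CV by default, objective = mean
CV Matthews correlation coefficient (MCC), best candidate refitted on the
full training subset.  The first candidate is always the library-default
configuration, so the tuned model never scores below the untuned default
on the same folds while keeping the 50 × 5 (+1 refit) fit count.  Declared
space: trees 50–1,000, depth 2–10, learning rate log-uniform 0.01–0.3,
subsample and column subsample 0.5–1, min child weight 1–10.  All package
XGBoost estimators use `tree_method="hist"` with `max_bin=64`: with a few
hundred rows and thousands of features split scanning is bin-bound, and 64
quantile bins resolve every split a 300-row training set can support.

## Evaluation

TP% = 100·tp/(tp+fn), TN% = 100·tn/(tn+fp), precision, F1, MCC, with
hit as the positive class.  Degenerate denominators (e.g. the rest set has
no positives) report 0 with a flag rather than raising.  Confidence
intervals are percentile bootstrap: (truth, prediction) pairs resampled
with replacement uniformly, 10,000 resamples by default, interval at the
2.5/97.5 percentiles.  Printed tables truncate (not round) to two
decimals — 229/238 = 96.218… prints as 96.21 — while serialized reports
keep full precision.

## Interpretation

Per-observation additive attributions come from XGBoost's native TreeSHAP
(`Booster.predict(pred_contribs=True)`); the module owns only the
top-k ranking by mean |attribution|, grouping (family, sensor, frequency
band split at 150 Hz — psd features only) and serialization.  Additivity
(attributions + base value = margin) is asserted per observation in the
tests.  Attributions are conventionally computed on the validation subset.

## The synthetic corpus

The simulator defines the study conditions; its defaults are fixed, not
tuning knobs:

* ~10:1 class imbalance (`hit_fraction = 0.115`), artifact mix 50 % chewing
  / 30 % yelling / 20 % handling;
* **impact**: exponentially damped sinusoid, amplitude 10–150 g, dominant
  frequency 20–150 Hz, amplitude halving every two cycles (so several
  oscillations survive the triage filter's settling time), coupled gyro
  pulse at 8 dps per g along a random axis;
* **chewing**: 3–6 Hann-windowed bursts, carrier 25–80 Hz, 11–25 g, plus a
  15 % mouthguard-deformation ripple whose frequency is drawn per event
  (350–600 Hz);
* **yelling**: 400–700 Hz narrowband under a 150 ms envelope, 10.5–13 g —
  above the raw trigger, below the filtered threshold (see the
  rectification note above);
* **handling**: 2–5 half-sine spikes of 3–6 ms at 15–60 g;
* ±1 % per-sensor sampling-rate jitter; 0.2 g white sensor noise; ADC
  clipping and quantisation; a random per-device rotation that the
  calibration matrices undo; 10 % of captures assigned to a separate
  holdout session.

Rotational coupling is deliberately comparable across impact, chewing
(jaw rotation) and handling (hand rotation).  Early versions gave
artifacts near-zero gyro coupling; total gyroscope power then separated
the classes on its own, and the classifier keyed on the *resampling image
band* of the upsampled gyro (>400 Hz bins) — an artifact of the upsampler,
not of head kinematics.  With overlapping rotational energy the
discriminative information concentrates in sub-150 Hz structure, which is
the regime the pipeline is designed around.

What the simulator does **not** emulate: biofidelic skull/neck dynamics,
lever-arm differences between the three accelerometer positions,
position- or sex-specific impact kinematics, multi-impact captures with
complex overlap, or real vocalisation spectra.  Passing the end-to-end
tests therefore demonstrates that the pipeline's machinery is correct and
that its stages compose as designed — not that the classifier would reach
the same numbers on real match data.

## Problem sizes used for validation

The package's end-to-end validation study
(`PipelineConfig.synthetic_study`) uses a 2,000-capture corpus at the
reference imbalance, 100 shared kernels per signal, a 20-candidate × 5-fold
search and 2,000 bootstrap resamples — sizes chosen so the whole study runs
comfortably on a single CPU while leaving the class structure identical to
the reference configuration (300 kernels, 50 candidates, 10,000 resamples),
which remains the default of the individual functions.

## Numerical choices and degenerate inputs

* z-score and standardiser epsilon 1e−12; PSD log floor 1e−30.
* Calibration matrices checked orthonormal to 1e−9 with determinant +1.
* Signals shorter than one Welch segment fall back to a single-segment
  periodogram (logged).
* Splitting requires each class to fill three non-empty parts; balancing
  requires both classes present; tuning requires each training class to
  have at least `folds` members.
* Selection ties are logged; sweep failures are recorded per algorithm and
  do not abort the sweep.

## Known limitations

* The JSON session format favours inspectability over size; a binary
  columnar backend would be the natural extension for large corpora.
* The 720-vs-7,200 kernel-feature ambiguity in the design lineage is
  resolved by making the per-signal kernel count configurable; the
  reference configuration uses 300 kernels (600 features/signal).
* Bootstrap CIs are percentile, not BCa; at the subset sizes used here the
  difference is below the reporting precision.
* The trigger emulator assumes a single device per stream set; multi-device
  sessions are handled at the corpus level.
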