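# Methods

## Scope and model

The package simulates the decoding side of a closed-loop EEG → ultrasound
neurostimulation system: single-channel EEG is filtered causally, cut into
non-overlapping 3 s windows, summarized by per-window features, classified
by a two-tier threshold rule, and seizure decisions drive a burst-train
stimulation state machine. Stimulation is recorded but never alters the
simulated EEG: the package models the decoder and controller, not the
physiological effect of vagus-nerve ultrasound. Consequently sham and
closed-loop runs on the same recording produce identical decision logs by
construction (and a test asserts it).

## The multi-level threshold detector

Given training seizure epochs, stage-1 thresholds are the per-feature
minima of {CL, STD, E_log} and stage-2 thresholds the per-feature means.
A window is seizure if all three features strictly exceed stage 1, or at
least two strictly exceed stage 2. Notes on the rule as implemented:

- Comparisons are strict. The training epoch that attains a per-feature
  minimum therefore fails the stage-1 path on that feature; it is still
  detected whenever it exceeds the other two stage-2 means (the
  two-of-three path). This edge case is unit-tested explicitly.
  Because the three features share physical drivers (all respond to
  discharge amplitude), the minimum-attaining epoch is often below two
  means as well, so training sensitivity of exactly 100% is not an
  invariant of the rule and is not asserted.
- The rule is monotone: increasing any feature can never turn a seizure
  decision into a non-seizure decision (property-tested).
- Thresholds may be fitted on raw or on range-normalized features; the
  fitted space is recorded in the model and checked at classification
  time, so a model is never silently applied in the wrong space.
  Normalized is the default. Since the normalization map is affine and
  increasing, the two modes give identical decisions when fitted on the
  same data; the flag exists because an online system must apply the
  training-time map to streaming data (no clipping — future extrema are
  unknowable online).
- Deployment consistency matters: a model used by the streaming controller
  must be fitted on epochs that went through the same causal band-pass.
  The test suite fits its "online" model on filtered, segmented data for
  exactly this reason.

## Features

For a window x(i), i = 1..N:

- CL = Σ|Δx| (line length), STD = sample standard deviation (N−1),
  Euclidean norm = √Σx², E_log = Σ log(x² + ε) with ε = 1e−12 µV²
  (configurable) guarding zero samples. Natural logarithm throughout; the
  base cancels out of threshold fitting and classification.
- Mean instantaneous frequency (MIF) = time average of the spectral
  centroid over a Hann short-time spectrogram; mean spectral entropy
  (MSE) = time average of the per-slice Shannon entropy of the normalized
  power spectrum, divided by log(#bins).
- Spectrogram slices are min(N, 4·fs) samples with 50% overlap. Short
  slices were rejected after measurement: with 32-sample windows at
  125 Hz a pure tone's entropy exceeds 0.3 and white noise falls below
  0.9, i.e. the estimator cannot distinguish the regimes it exists to
  distinguish. With the adopted slice length MIF recovers 4 and 10 Hz
  tones to well under 0.5 Hz and white-noise MIF sits within a few
  percent of fs/4 (the centroid of a flat spectrum).
- Inside the entropy only, adjacent frequency-bin pairs are averaged
  before normalizing. Raw periodogram bins fluctuate (exponentially
  distributed for Gaussian inputs), which biases spectral entropy low by
  ≈ (1−γ)/log(#bins) ≈ 0.1 — enough to drag white noise below 0.9. Pair
  averaging halves that bias at negligible cost in tone concentration
  (tone MSE ≈ 0.22, white-noise MSE ≥ 0.93 over 40 seeds).

## Synthetic EEG generator

The generator emulates the statistical structure of rodent EEG in an acute
chemoconvulsant seizure model — the structure a threshold detector keys
on — with no claim of biophysical fidelity.

- **Baseline**: 1/f-shaped Gaussian noise (1 Hz knee) band-limited to
  0.5–45 Hz, standard deviation `baseline_sigma` (default 20 µV, a nominal
  rodent scalp-screw amplitude).
- **Events**: `n_seizures` (default 5) per 30-minute recording, durations
  uniform in 21–60 s, placed without overlap with ≥ 10 s gaps; annotations
  record the injected intervals exactly.
- **Ictal waveform**: a stereotyped ~3 Hz train of sharp biphasic spikes
  (12 ms Gaussian-derivative, amplitude jitter U(0.95, 1.05), period
  jitter U(0.98, 1.02)) plus a 1.5 Hz slow wave at 0.6 of the spike peak,
  plus broadband noise at 2× baseline sigma. Peak amplitude is
  `seizure_amplitude_ratio` × `baseline_sigma` (default 12, i.e. an order
  of magnitude above baseline). Spikes, wave and noise each carry an
  independent "waxing-waning" envelope: mostly at ceiling, with brief
  (~1 s) attenuations of ~55% when a slow Gaussian process crosses 2σ.
  Three design choices deserve explanation:
  - the wave is detuned from the spike rate (1.5 vs 3 Hz): an exactly
    spike-locked wave makes the spike/wave phase alignment a hidden
    per-epoch amplitude factor that artificially couples all features;
  - the discharge is scaled by a fixed nominal factor rather than
    normalized to its realized maximum, so event amplitude does not hinge
    on one extreme sample;
  - the three envelopes are independent, reflecting that spike sharpness,
    slow-wave amplitude and background activation fluctuate separately in
    real discharges; for the detector this means a brief dip in one
    feature leaves the other two informative, which is what makes the
    two-of-three stage-2 path useful.
  Events start and stop with 0.5 s cosine ramps for continuity.
- **Epoch datasets** pool epochs across as many independently seeded
  recordings as needed (as one would pool animals): seizure epochs are cut
  from the steady ictal interior of events (the edge ramps are transition
  zones, not steady seizure activity), non-seizure epochs from grid
  windows with zero annotation overlap. Whole-recording segmentation, by
  contrast, labels each grid window seizure iff ≥ 50% of its samples fall
  inside an annotation — the labeling rule an online system would face.
- All randomness flows from one seed through one generator stream;
  identical config + seed is bit-identical (tested).

What the generator does **not** emulate: artifacts (movement, chewing,
electrode pops), inter-animal variability, circadian/state changes,
post-ictal suppression, or any effect of stimulation on the EEG. Passing
tests on this generator therefore demonstrate the correctness and internal
consistency of the pipeline — causality, thresholds, burst bookkeeping,
scoring — not field performance on real recordings, where artifact
rejection and per-animal threshold fitting would dominate error rates.

## Detector benchmark

The benchmark protocol draws 100 seizure + 100 non-seizure 3 s epochs,
splits them 8:2 stratified (160 train / 40 test, 80 training seizure
epochs), fits thresholds on the training seizure epochs, classifies the
held-out 40, and averages accuracy over five independent seeded cycles.
On the default generator this yields mean accuracies in the high-98s to
100% depending on the master seed (99.5% at the canonical seed used in the
tests). The residual errors are false negatives with a known origin: a
fresh test epoch falls strictly below an 80-sample training minimum with
probability ≈ 1/81 per feature regardless of how tight the class is (a
rank statistic), and such an epoch is only recovered when the other two
features clear their stage-2 means. This is a property of min/mean
threshold rules generally, not of the implementation.

## Controller

- Decisions are emitted at window end, so onset-to-trigger latency is in
  (0, 2·window_s] depending on where the onset falls relative to the grid
  and the 50% labeling rule.
- An episode is at least `stim_duration_s` (default 60 s) of 5 s-on /
  5 s-off bursts (protocol SD/ISI); a non-multiple duration truncates the
  final burst. With `retrigger` enabled the episode stays open while
  decisions remain seizure and closes at the first non-seizure decision
  after the minimum; without it, new episodes require a new trigger after
  the previous episode ends.
- The random comparator triggers each 3 s tick with probability
  n_triggers / n_ticks — a matched *expected* dose, the documented
  interpretation of dose-matched random stimulation.
- Causality is enforced structurally (one pass, persistent filter state)
  and verified by corrupting future samples in a test.

## Evaluation

Sen = TP/(TP+FN), Spe = TN/(TN+FP), Acc = (TP+TN)/total, in percent;
a metric with a zero denominator is reported as undefined (None), never as
0. Event-level scoring merges seizure-classified windows separated by at
most one non-seizure window (debouncing) into detected events, matches
them to annotations by overlap (optionally tolerance-expanded), and
reports counts, durations, mean onset latency, misses and false
detections.

## Numerical and interface choices

- Filtering uses scipy second-order sections; the online path is
  single-pass (causal), the offline path optionally zero-phase.
  The default band is 0.5–45 Hz: at 125 Hz sampling a 70 Hz upper edge
  would sit above Nyquist, so the acquisition band is capped below it.
- EDF files are written by a minimal built-in single-channel writer
  (16-bit, 1 s records, µV) and read back via mne; the round trip is
  tested against mne's reader at 16-bit quantization accuracy.
  Annotations travel in a separate CSV rather than EDF+ annotations.
- Threshold models persist as human-readable JSON (six numbers plus
  metadata); the SVM comparator stays in scikit-learn's ecosystem.
- The recurrent (LSTM) comparator is an optional extra requiring a
  deep-learning backend; without one it raises a documented error rather
  than failing silently. The package's results do not depend on it.
- Problem sizes throughout (30-minute recordings, 200-epoch datasets,
  five-run benchmarks) were chosen to mirror the modelled experiment while
  keeping any single analysis in the seconds range.
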