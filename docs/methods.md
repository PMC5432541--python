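# Methods

This note documents the models behind `srpsearch`: what the synthetic
generator emulates, the analysis chain's numerical choices, the defaults
and their rationale, and what passing tests do and do not establish.

## Task and behavior model

The monitoring task highlights each of 15 grid locations (3 rows x 5
columns) exactly once per trial for 1.027 s, in a pseudo-random order
constrained so consecutive highlights differ by at most two steps in one
grid direction and one in the other. The sampler first tries rejection
sampling of unconstrained permutations (50 attempts), then a greedy walk
that picks a uniformly random admissible unvisited location and restarts
on dead ends; on the 3 x 5 grid dead ends are rare and the sampler has
never been observed to exhaust its bound. Each trial holds 2, 3 or 4
targets, uniformly chosen, at uniformly random serial positions.

Behavior: each target is missed independently with probability
`base_miss_prob(load) * c[serial_pos]`, where the serial-position curve
`c` is a raised cosine (low at the trial ends, high in the middle —
primacy/recency) normalised to mean 1 so that the expected hit rate
equals `1 - base_miss_prob` exactly. The bases (0.04 low load, 0.27 high
load) anchor mean hit rates at 0.96 and 0.73. A miss spawns a false alarm
at a random non-target location with probability 0.35 — misses mostly go
unaccompanied, so sessions under-report targets on balance. Math-task
answers are correct with a fixed probability (0.62); no cognitive model
of arithmetic is attempted, and math accuracy is used only for the
(expectedly null) correlation with monitoring performance.

The inter-trial gap defaults to 20 s. It stands in for the reporting
phase (clicking up to 15 boxes, typing the math answer), during which
gaze drifts back to screen centre. The gap matters beyond realism: the
saccade-candidate threshold is a multiple of the velocity-trace SD, which
is dominated by the saccades themselves, so the duty cycle of saccades
sets the detectability of the smallest (one-column) saccades.

## Signal generator

All streams share t = 0; EEG/EOG are synthesized at 512 Hz (so the
resample-to-256 step is exercised), eye streams at 60 Hz.

**Eye movements.** Per highlight a saccade latency is drawn from a normal
distribution per (load, condition) with means/SDs set to the study
conditions — hit 154/38, miss 267/245, non-target 165/45 ms under low
load; hit 199/43, miss 284/97, non-target 229/53 ms under high load —
truncated to [105, 795] ms so the true saccade stays inside the
detector's 100-800 ms window (the truncation shifts the miss population
mean upward by a few ms; recovery is therefore always scored against the
generator's own annotations, not the configured means). Eye position
follows a logistic sigmoid whose midpoint defines the ground-truth
peak-velocity time. The rise time follows the saccadic main sequence
(duration ~ 21 + 2.2 ms/deg): a 10 deg saccade takes ~43 ms, a 28 deg
(two-row) saccade ~83 ms. The amplitude-dependent rise is both more
physiological than a fixed rise and necessary for the analysis chain to
behave as in the real study: with a fixed fast rise, the 2-100 Hz
transient of a large vertical step is indistinguishable from a blink for
the 3 x SD blink rule (the ratio transient/threshold is invariant to
amplitude scaling), and those saccades would be interpolated away.

After a condition-dependent dwell (means: hit 950, non-target 870, miss
800 ms; SD 110 ms), gaze drifts off the stimulus at sub-saccadic speed
(190 px over 400 ms) to a resting point perpendicular to the upcoming
transition — chosen so the rest position never shadows the direction of
the next saccade — ending the measurable fixation. Misses additionally
truncate their own fixations via their late saccades, reproducing the
"arriving late" account of short miss fixations.

**EOG.** HEOG/VEOG are the horizontal/vertical gaze angles (positive
rightward/upward; rows grow downward, so the vertical transition sign is
`-sign(delta_row)`) times a gain of 12 uV/deg, plus white noise (3 uV),
noise spikes (2/min, +/-1200 uV, 3 samples) and, on VEOG, blinks:
raised-cosine bumps at Poisson times (15/min), width 150-400 ms,
amplitude 400 uV +/- 20%. The amplitude ordering is deliberate: spikes
well above the 5 x SD despike threshold, blinks below it (so they reach
the blink detector, whose 3 x SD threshold needs blink energy in the
filtered trace to sit above saccade-step transients), saccade steps below
both.

**EEG.** Per channel, 1/f^alpha background (alpha = 1, SD 9 uV) plus
white noise (3 uV). Each highlight injects a half-cosine "P300" bump
(width 0.3 s) centred 0.5 s after the true saccade peak, amplitude 5 uV
for targets and 1 uV for non-targets, spatially weighted 1.0 over the
parieto-central set, 0.5 over its neighbours, 0.15 elsewhere. Miss
amplitude defaults to the target amplitude, reflecting the finding that
miss SRPs overlap hit SRPs; it is configurable for power studies. No
ocular artifact propagation into EEG channels is modelled (corneo-retinal
dipole modelling is out of scope), so EOG-feature classification carries
no target information by construction.

**Pupil.** Baseline 4.3 mm (low load) / 4.7 mm (high load) — the study
reports diameters "around 4.5 mm" without printing the load difference,
so the split is a documented choice — plus a slow Gaussian-filtered drift
(SD 0.2 mm, 5 s timescale), white noise (0.1 mm), and +0.15 mm during the
2 s window of subsequently missed targets (momentary workload). Gaze
carries fixation scatter (8 px), per-sample jitter (6 px), a configurable
affine miscalibration (identity by default) and invalid samples (2% plus
blink intervals).

`SignalParams.null()` and `BehaviorParams.null()` remove every
condition effect (equal latencies, dwells, amplitudes, baselines; flat
serial-position curve; equal miss rates) for null calibration.

## Analysis chain: numerical choices

* Threshold SDs (despike 5x, blink 3x, candidates 4x, bad channels 5x,
  epoch outliers 50x) are computed globally over the relevant trace —
  deterministic and simple; no windowed variants.
* Despiked runs are padded +/-50 ms, blink runs merged across <100 ms
  gaps and padded +/-100 ms; all cuts are linearly interpolated between
  flanking clean samples (endpoints held). Blink detection is one-sided
  (positive; blinks are positive VEOG deflections) and ignores runs
  shorter than 30 ms — a physiological blink lasts >= ~100 ms, and
  without a width floor any 3 x SD rule flags isolated noise samples.
* The velocity kernel is a derivative of Gaussian, sigma 8 samples at
  256 Hz (~31 ms), truncated at +/-4 sigma, normalised so a unit-slope
  ramp maps to 1, evaluated with reflected padding.
* Candidate runs merged across <20 ms gaps; one candidate per run at the
  argmax of |v|. Selection searches HEOG first; purely vertical
  transitions (and failed horizontal matches) fall through to VEOG. For
  the first highlight of a trial the "previous location" is the screen
  centre, where gaze rests between trials; a first highlight at the
  centre cell has a zero transition and is counted unmatched.
* EEG order is fixed: resample (polyphase) -> bad-channel detection on a
  0.5-32 Hz copy -> inverse-distance interpolation (4 nearest good
  channels, standard 10-20 positions via mne) on unfiltered data ->
  average reference over good channels (unfiltered) -> 4th-order
  zero-phase Butterworth bandpass -> epochs [t0, t0 + 1 s) at 256
  samples -> baseline = mean of the first 25 samples -> rejection of
  epochs whose per-channel SD exceeds 50 x the across-epoch median for
  that channel.
* Average referencing attenuates the injected parieto-central bump by
  the mean topography weight (0.445), so the recoverable target minus
  non-target difference is (5 - 1) x (1 - 0.445) ~ 2.2 uV; recovery
  tests assert against this analytic expectation, not the raw 4 uV.
* Gaze recalibration fits a global least-squares affine map from the
  median gaze over [onset + 0.3 s, onset + 1.0 s] of each highlight (the
  first 300 ms are pre-saccade) to the true centres; collinear anchors
  fall back to translation with a warning. Fixation duration is the
  valid on-stimulus sample count divided by the eye rate (robust to
  dropouts); pupil size is the mean over those samples, with a median
  option exposed.
* Pointwise SRP tests are two-sided paired t-tests across participants
  at every sample, alpha 0.05, with Benjamini-Hochberg applied over the
  full 1 s epoch per contrast; participants missing a condition are
  excluded pairwise. Hit/miss contrasts are evaluated in the high-load
  condition only when a participant has >= 10 misses (low load rarely
  qualifies, mirroring the study design).
* Classification: per fold, features are standardized with training-fold
  mean/SD (zero-SD features mapped to 0), the training majority class is
  subsampled without replacement to the minority count, and a linear SVM
  (C = 1, unspecified in the source pipeline) is fitted; folds are
  stratified (plain splits can empty the rare class). Accuracy is pooled
  correct/tested (fold-mean also reported); above-chance is the exact
  one-sided binomial tail against 0.5 at alpha 0.05 on the pooled count.

## Study sizes

Simulation studies default to 2 blocks x 8 trials per load per
participant (240 highlights, ~48 targets, ~13 misses under high load)
and 20 participants — large enough for every directional effect and the
miss-count guard, small enough that a full study runs in minutes. The
full-size session (8 blocks x 11 trials) remains available through
`ExperimentConfig` defaults.

## What passing tests show — and don't

The generator reproduces the *statistical structure* the pipeline
assumes: condition-dependent latency/dwell/pupil shifts, a spatially
weighted additive ERP, artifact amplitudes in realistic ratios, shared
clocks. Passing recovery and effect-direction tests therefore shows the
chain is correct and well-calibrated on data with exactly these
properties. It does not show robustness to what the generator omits:
ocular artifacts inside EEG channels, non-stationary noise, head
movement, smooth pursuit, asymmetric or multi-peaked blink shapes,
tracker-specific gaze error fields, or real P300 latency/amplitude
variability across trials and participants. Classification accuracies on
synthetic data depend directly on the injected effect sizes and should
be read as pipeline checks, not performance claims about real
recordings.

## Known limitations

* Recording I/O uses an HDF5 container with 16-bit quantization plus
  plain-text tables rather than a clinical interchange format.
* The velocity-SD candidate threshold makes the smallest (one-column)
  saccades sensitive to the session's saccade duty cycle; very short
  inter-trial gaps degrade detection of those saccades.
* The blink detector's SD is partly transient-driven; on blink-free
  vertical EOG it can flag the largest vertical saccade steps. This is a
  property of the fixed-multiplier rule itself and is visible in the
  test suite's exclusion of cleaned intervals from the noise-free
  peak-exactness check.
* `BehavioralOutcome` does not model the reporting phase's timing or
  click kinematics; false alarms are placed uniformly at random.
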