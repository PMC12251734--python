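# Methods

`cbeqc` analyses movement quality in chair-based exercise (CBE) for older
adults from two signal streams: 2D pose landmarks captured by a single
camera, and single-channel surface EMG (sEMG).  Because no public
recordings of this protocol exist, the package ships a synthetic-cohort
generator calibrated from a published summary table of 20 community-dwelling
older adults (per movement and condition: mean ± SD of the target joint
angle in degrees and of the overall mean sEMG RMS in mV).  Every downstream
stage is exercised and validated against that calibration.

## Joint-angle kinematics

Landmarks follow the MediaPipe convention: normalized image coordinates,
origin top-left, y increasing downward, at 30 fps.  Eight keypoints are
used: shoulders (IDs 11/12), hips (23/24), knees (25/26), ankles (27/28).

Two angle primitives are defined:

* **Vertex angle** at the middle point `b` of a chain `a–b–c`:
  `θ = arccos(⟨a−b, c−b⟩ / (‖a−b‖‖c−b‖))`, in [0, 180]°.  The cosine is
  clamped to [−1, 1] before `arccos` so collinear configurations are exact.
  The angle is invariant to translation, rotation and uniform scaling
  (property-tested).
* **Segment inclination** of `p→q` against the image vertical: the unsigned
  angle between the directed segment and the *downward* vertical axis, in
  [0, 180]°; swapping the endpoints folds the angle to its 180° complement.
  The downward reference is fixed by the convention that a segment pointing
  down the image has inclination 0°.

The default registry holds six named angles — left/right shoulder–hip–knee
(hip), left/right hip–knee–ankle (knee), left/right knee–ankle inclination —
and is configurable via YAML.  The published figure defining the six angles
is not machine-readable, so the registry is a surrogate consistent with the
exercise descriptions; the lower-leg (knee–ankle) inclination is the primary
M5 feature, and the hip–knee–ankle vertex is also available where a vertex
reading of "knee–ankle angle" is preferred.  Per-repetition summaries are
plain frame averages.

## sEMG conditioning chain

Fixed order: 50 Hz notch → 20–450 Hz bandpass → windowed RMS.  The source
protocol specifies the notch frequency, band edges, sampling rate
(1000 Hz), window length (100 ms) and overlap (50%) but not filter order or
phase handling; the package uses a second-order IIR notch with Q = 30 and a
4th-order Butterworth, both applied forward–backward (zero phase), which is
standard sEMG practice.  Response contracts are asserted by measured
sine-in/sine-out ratios at 5, 50, 100 and 490 Hz on the steady-state
(central) part of the signal, since zero-phase filtering leaves edge
transients that are not part of the frequency response.

Windowed RMS uses `floor((N − W)/H) + 1` windows (W = 100 samples,
H = 50); trailing samples that do not fill a window are dropped.  Summary
statistics (overall mean RMS; per-repetition peak RMS) are computed on this
raw envelope.  For visualization and cross-trial alignment only, the
envelope's window index is mapped affinely onto (0, 1), linearly resampled
to 500 points and smoothed with a unit-area Gaussian (σ = 10 samples of the
500-point grid, reflective boundaries).

Repetition segmentation is needed because the protocol (10 repetitions per
~20 s trial) does not include event markers.  When ground-truth markers are
available (e.g. from the generator) they take precedence; otherwise the
envelope is smoothed (σ = 5 windows), thresholded at the midpoint of its
10th and 90th percentiles, gaps shorter than 0.25 s are merged and segments
shorter than 0.25 s dropped.  A detected count different from the expected
one raises an error carrying the count, so callers can decide whether to
relax.  Peak extraction uses the raw (unsmoothed) envelope.

## Windowed features

Angle series are cut into 30-frame windows (1 s at 30 fps) with a 15-frame
hop.  Per window: mean, minimum, maximum, median (midpoint convention for
even windows) and SD in the time domain, plus mean/peak/minimum power, SD
of power and median frequency from a Welch PSD.  On a 30-sample window the
Welch estimate degenerates by design to a single Hann-tapered,
mean-detrended segment; sub-segmenting would leave ≤ 2 Hz resolution and
was rejected.  The nominal 1–20 Hz analysis band exceeds the 15 Hz Nyquist
limit at 30 fps and is clipped to [1, fps/2); median frequency is the
smallest in-band bin at which cumulative in-band power reaches half the
total.  SDs use the population convention (denominator n) consistently
inside windows; across-participant summaries use the sample convention
(n − 1) since they estimate cohort spread.

## Classification and evaluation

An RBF-kernel SVM (C = 1, gamma = 1/(n_features · feature variance),
class weights inversely proportional to class frequencies) on standardized
features.  Leave-one-out cross-validation is available at two
granularities: *sample* (each window held out once — the reference
protocol) and *participant* (each participant's windows held out together),
reported side by side where leakage matters.  Standardization is refit in
every fold.  Decision-boundary ties predict class 1 (correct).

A degenerate case worth knowing: with identical feature vectors and exactly
balanced labels, sample-level LOOCV with balanced class weights reports
perfect accuracy, because the held-out sample's class is always the
training-fold minority and the fold predicts it.  This is a property of the
protocol, not a bug; chance-level behaviour (≈ 50%) appears as soon as the
uninformative features carry independent noise.  The suite pins both
behaviours.

## Group statistics

Trial-level summaries (mean angle, mean RMS) are averaged to
per-participant means, then to across-participant condition summaries
(mean ± sample SD).  Correct-vs-incorrect contrasts use two-sided paired
t-tests on per-participant means of the raw envelope; raw p-values are
reported alongside Holm-adjusted ones (the adjustment is additive output,
flagged as such).  Identical paired vectors return t = 0, p = 1; a
zero-variance difference with nonzero mean raises, since t is unbounded
there.  Quantiles in the box-plot tables use linear interpolation between
order statistics.  Plot rendering is out of scope; the module emits the
tidy tables behind the usual waveform/box/scatter figures.

## Synthetic cohort generator

The generator's defaults are the study conditions: 20 participants, 10
trials per condition, ~20 s trials, 30 fps video, 1000 Hz sEMG, 10
activation bursts per trial, 50 Hz powerline contamination.

**Angles.**  The printed per-movement SDs are across-participant spreads,
so they parameterize the participant level: `mu_p ~ N(mean, sd_between)`
once per participant, and frame-level jitter `eps_t ~ N(0, sd_within)` with
`sd_within = 0.5°` by default (landmark-jitter scale; the source reports no
within-trial variance, so this is an exposed surrogate).  The landmark
builder keeps a static plausible base pose and re-places the distal point
of the target angle each frame so that the registry angle computed from the
output equals `mu_p + eps_t` exactly; realizations outside (0, 180] are
clipped with a logged warning.  Noiseless round trips are exact to 1e-6°.
The classification surrogate design folds the printed SD into frame jitter
(`sd_between = 0`, `sd_within` = printed SD), making window features
stationary across participants.

**sEMG.**  Each trial is a Hann-windowed burst train (duty cycle 0.6) over
a unit-RMS band-limited (20–450 Hz) Gaussian carrier.  The conditioning
chain is positively homogeneous, so passing the clean train through it once
yields a closed-form scale factor `target / mean_rms(chain(clean))` that
calibrates the overall post-pipeline mean RMS to the participant's strength
exactly; 50 Hz powerline (default amplitude 0.02 mV, removed by the notch)
and Gaussian baseline noise (default SD 0.005 mV) are added afterwards.
Participant strengths are (correct, incorrect) pairs from a bivariate
normal with the calibration means/SDs and correlation 0.8, floored at
0.005 mV to keep amplitudes positive.

**Reproducibility.**  One master seed is fanned out through counter-based
sub-seeds keyed by (participant, movement, condition, repetition, stream),
so any trial regenerates identically in isolation and cohorts are
byte-stable under a fixed seed.

**What the generator does not emulate:** pose-estimation failure modes
(occlusion, identity switches, depth ambiguity at a 45° camera), movement
phase structure within a trial (angles are stationary around `mu_p` rather
than cyclic), electrode artifacts, and MVC-scaled amplitudes.  Passing
tests therefore demonstrate that the pipeline recovers the statistical
structure it assumes, not that the published accuracies would replicate on
new real recordings.

## Problem sizes in the verification runs

`scripts/acceptance.py` runs the two classification targets at reduced
size — M5 at 20 participants × 3 trials × 10 s (2,280 windows), and the
nine-movement sweep at 20 × 2 × 6 s (880 windows per movement) — because
sample-level LOOCV cost grows roughly cubically with window count while the
per-window feature distributions, and hence the attainable accuracy, do not
depend on it.  The paired-test, angle-recovery and sEMG-recovery targets
run at the full cohort size (n = 20).  The pytest suite uses smaller
cohorts of the same structure.

## Known limitations

* The six-angle registry and the movement→angle assignment are surrogates;
  both are configurable and all printed-mean round trips hold for any
  assignment.
* Within-trial angle variance and sEMG SNR are not published; the defaults
  above are explicit configuration, not estimates.
* The published hold-out accuracy (97.48%) and the exact per-class supports
  of the reference report depend on the private dataset split and are not
  reproduced; `holdout_eval` leaves the split to the caller.
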