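# Methods

This note documents the models behind `bciloop`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter when reproducing results.

## The problem being simulated

After a subcortical stroke, a person may retain motor-cortical activity
that no longer reaches the hand.  An intracortical BCI records that
activity (spiking and high-frequency field potentials from
microelectrode arrays in precentral gyrus), decodes attempted hand
movement in real time, and drives the hand motor of a powered
elbow-wrist-hand orthosis.  The alternative control path is myoelectric:
the orthosis compares rectified-RMS EMG envelopes against manual
thresholds.  In the post-stroke arm this path is handicapped by
spasticity — wrist flexors and extensors co-contract, wrist flexors
couple abnormally to biceps, and flexor tone persists after effort — so
the motors must oppose retained tone whenever the user tries to open the
hand.  The package reconstructs this whole loop on synthetic data and
measures the functional consequence: hand release times and ARAT-style
outcome scores per control mode.

## Synthetic generators (the study conditions)

**Intent traces.**  Session scripts are lists of (label, duration)
epochs on a 20-ms grid; `rest` maps to hand intent 0, attempted hand
actions to 1.  No reaction-time jitter or fatigue is modeled.

**Spike trains.**  Channel c fires an inhomogeneous Poisson process with
rate `max(0, baseline + gain_c · intent(t))`, realized by thinning.
Defaults: 256 channels, 87 tuned (drawn per config seed with random
sign), baseline 10 spikes/s, |gain| 20 spikes/s — a linear-rectified
tuning model; the tuning distribution across channels is deliberately a
free config, not an asserted fact.  Spike-band voltage, when rendered,
is white Gaussian noise (20 µV SD) plus a 1-ms biphasic template with
peak 10× the noise SD; only threshold-crossing detection needs to work
on it, so no waveform realism beyond that is attempted.

**LFP.**  Amplitude-modulated white Gaussian noise with a flat one-sided
PSD equal to the configured band power at every frequency: rest
1.5 V²/Hz (inside the 0.5–3 V²/Hz resting range), attempted movement
12 V²/Hz, switching per 20-ms intent sample.  A flat PSD P at sampling
rate fs requires sample variance P·fs/2.  No oscillatory phase
structure, 1/f shape or line noise is modeled — the trigger consumes
power only, and the generator/feature pair is calibrated through the
shared Parseval identity.

**EMG.**  Four envelope channels (wrist flexor/extensor,
biceps/triceps) on a 100-ms grid, generated directly as rectified-RMS
envelopes (no raw-EMG stage, since the orthosis consumes RMS).  The
extensor receives `cocontraction_gain` times the flexor envelope and the
biceps `synergy_gain` times the flexor drive — the two post-stroke
couplings — both 0.5 by default; envelopes are clipped at zero.

**Synthetic participant.**  For decoder calibration, 40 feature channels
fire Poisson counts in 200-ms bins at `clip(10 + g_c · drive, 0, 200)`
spikes/s with g_c ~ N(0, 8²); drive is the displayed cursor target plus
`feedback_coupling` times the prediction cursor when one is shown.  The
200-spikes/s ceiling is a physiological bound that also keeps
positive-feedback loops finite.

What passing tests on these generators show: the pipeline recovers what
it assumes — configured rates, powers, couplings and mappings — at
realistic sizes and SNRs.  What they do not show: robustness to
nonstationarity, electrode loss, movement artifact, oscillatory
confounds or behavioral variability, none of which the generators emit.

## Feature extraction

Spike thresholds are `multiplier × RMS` with multiplier −4.5
(negative-going crossings, the extracellular convention) and RMS taken
over the whole calibration segment — a running RMS would also be
defensible; the block form is simpler and exposed in config.  Detection
uses first-sample crossing with a 1-ms lockout.  Counts use half-open
bins [t, t+0.2 s).  The leaky integrator is the first-order form
r_t = r_{t−1}·e^(−Δ/τ) + c_t with τ = 0.5 s by default; its constant
-input steady state c/(1 − e^(−Δ/τ)) anchors the tests.

Band power is the one-sided periodogram with rectangular taper (the
plain periodogram default; no Welch/multitaper averaging), averaged
within eight 50-Hz bins over 100–500 Hz, then across bins.  Windows are
1 s long, end-aligned (causal — the system being modeled ran in real
time), stepped every 500 ms.  100–500 Hz is the operative band because
the 10 V²/Hz trigger is defined on it; other bands (e.g. 100–1000 Hz)
are reachable through `BandPowerConfig`.  Channel ranking uses the
absolute standardized mean difference of window values between movement
and rest windows with ties broken by channel index; the number of
channels averaged is a config (default 20) rather than a single asserted
value.  The trigger is a strict inequality: power exactly at threshold
does not close the hand.

## Decoders

The operative decoder is ridge least squares from lagged features (lags
0–4 bins of 200 ms, i.e. up to 800 ms of history) to a 1-D position
output.  Features are standardized inside the model (stored with it);
the penalty applies to standardized coefficients with default 1e-3,
equivalent to 1e-3 times the mean feature variance; the intercept is
unpenalized.  With ridge 0 a rank-deficient design is an error rather
than a silent pseudo-inverse.  Position (not velocity) output is the
exercised path; velocity targets for the Kalman variant come from finite
differences of the cursor trajectory.

The position–velocity Kalman filter is identified by least squares
(state transition A and process covariance W from state pairs,
observation matrix H and noise Q from state/observation pairs) and run
with the standard predict/update recursion; scalar updates are tested to
1e-10 against the conjugate-Gaussian closed form.  LDA uses pooled
within-class covariance with optional shrinkage toward a spherical
matrix; decision trees, SVM and k-NN are available through a factory
over scikit-learn behind the same fit/predict surface and are not
separately validated here.

**Two-stage calibration.**  Stage 1 fits on one open-loop minute of
triangle-wave tracking (5 s per screen traverse); stage 2 replays the
block with the stage-1 prediction displayed and fed back into the
participant, then refits on the closed-loop data.  When the participant
reacts to the prediction cursor, the open-loop filter's *gain* is wrong
in closed loop while its output stays correlated with the target —
correlation is scale-invariant — so the held-out metric on which
retraining shows its value is closed-loop tracking RMSE
(`closed_loop_tracking_error`), with correlation
(`closed_loop_tracking_corr`) reported alongside as the
scale-free quality score.

## Control rules and plant

The decision rules are implemented as printed decision tables with three
conventions fixed here because the sources leave them ambiguous:

- dual mode: Open iff flexors < FlexTh and extensors > ExtTh, Close iff
  the reverse; *everything else holds*, including exact threshold hits
  and co-contraction (the printed Hold clause is malformed — its
  disjunctions cover all inputs — so Hold is the complement of the other
  two, which matches the prose);
- open/close modes print strict inequalities both ways, leaving the
  boundary undefined; the boundary goes to the default posture (closed
  for open mode, open for close mode);
- the double-threshold rule's printed Hold interval is inconsistent with
  its own threshold ordering; it is implemented as
  AT₁ ≤ x_t < AT₂, with Extension below and Flexion at or above AT₂.

The plant is a rate-limited integrator: aperture in [0, 1], full travel
in 0.5 s (motor rate 2 aperture/s) by default.  Update rates follow the
signal each mode consumes: 10 Hz for EMG modes, 5 Hz for the filter
(200-ms bins), 2 Hz for the training-less trigger (500-ms updates).

**Closed-loop task.**  Each trial: close onto the object (to aperture
0.2), transport 2 s, arrive over the bin, open to aperture 0.7 →
release.  Release time is over-bin to the exact within-step
threshold-crossing instant, so an oracle decoder reproduces plant
kinematics exactly.  Myoelectric mode uses the close-mode rule on the
wrist flexor envelope; with spasticity on, flexor tone jumps to 0.55 V
on each grasp and decays with τ = 1.5 s during attempted opening, so
release waits for the tone to fall below the 0.3-V threshold — this is
the mechanism (motors opposing retained tone) that makes myoelectric
release slower than BCI release.  The elbow pathway is typed but not
simulated.

## Outcome scoring

ARAT totals are the sum of the 19 item scores (each 0–3); the module
validates ranges and item count only — administration rules live in the
fixture.  The release-time comparison defaults to the pooled-variance
(Student) two-sample t test with df = n₁ + n₂ − 2.  The variant matters:
on the packaged 33-vs-10 release times the pooled test gives p = 0.0408
while Welch gives p = 0.17; the pooled form is the one consistent with
the recorded result, and both are exposed via `equal_var`.  Serial
clinical scales (Fugl-Meyer 30/36/38, Motricity Index 48/61.5/75.5,
Stroke Impact Scale 232/269, Modified Ashworth) are stored reference
data: their item-level inputs are not available, so they are echoed, not
recomputed.

## Problem sizes and determinism

Statistical checks use sizes at which their expected sampling error is
comfortably inside the asserted tolerance: 100-s sessions for Poisson
rate recovery (3-SE bounds), 200+ windows for trigger rates, 100 windows
for PSD flatness (per-bin SE ≈ 1.4% against a 5% band), one-minute
calibration blocks, and 30 closed-loop trials per mode for the
release-time direction.  Every generator takes an explicit seed and
there is no global RNG state; scripts derive per-component seeds from a
single master seed.  File formats are plain text (CSV with headers,
JSON, JSON-lines session logs).

## Known limitations

Single-participant-style simulation only; no day-to-day nonstationarity,
visual neglect, or fatigue; LFP carries no spectral shape beyond the
piecewise-flat PSD; EMG has no raw-signal stage; the Kalman and LDA
paths are implemented and tested but the closed-loop task exercises the
linear filter and the training-less trigger, mirroring how the modeled
system was actually used.
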