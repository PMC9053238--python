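# bciloop

A fully simulated, desk-scale reconstruction of an intracortical
brain-computer-interface (BCI) pipeline for post-stroke hand control:
synthetic neural and muscle signals in, decoded hand open/close commands
out, with clinical-outcome scoring at the end.

## Who this is for

Researchers and students in neural engineering who want to study, test or
extend the signal chain of a BCI-driven powered hand orthosis without
access to human intracortical recordings.  Every stage runs on seeded
synthetic data with the statistical structure the real pipeline assumes,
so the whole loop — signal generation → feature extraction → decoding →
control → outcome scoring — is reproducible on a laptop.

## What is in the loop

- **Synthetic sessions** (`bciloop.synth`): cued intent traces;
  inhomogeneous-Poisson spike trains on a 256-channel array (87 tuned
  channels by default) with optional 30 kHz spike-band voltage rendering;
  broadband LFP whose 100–500 Hz power rises from a 0.5–3 V²/Hz resting
  baseline to >10 V²/Hz during attempted movement; 4-channel
  rectified-RMS EMG with post-stroke co-contraction and flexor-synergy
  coupling; triangle-wave cursor-training targets.
- **Spike processing** (`bciloop.spikes`): per-channel threshold at
  `multiplier × RMS` (default −4.5), crossing detection with 1-ms
  lockout, 200-ms binning, leaky integration
  r_t = r_{t−1}·e^(−Δ/τ) + c_t, max-normalization and cross-channel
  population sums.
- **High-gamma LFP features** (`bciloop.lfp`): one-sided rectangular-taper
  periodogram averaged in 50-Hz bins over 100–500 Hz, 1-s rolling windows
  updated every 500 ms; channel ranking by movement-vs-rest modulation;
  the training-less trigger (close the hand while mean band power
  >10 V²/Hz).
- **Decoders** (`bciloop.decoders`): ridge linear filter on lagged
  features x_t = wᵀφ(t) + b (lags 0–800 ms), a position–velocity Kalman
  filter, pooled-covariance LDA, and the two-stage cursor calibration
  (open-loop fit, then refit with the prediction cursor displayed).
- **Control** (`bciloop.control`): decoder discretization with one
  threshold (Extension if x_t < AT, else Flexion) or two (Hold band
  between AT₁ and AT₂); the myoelectric dual/open/close threshold modes;
  a rate-limited aperture plant; and a closed-loop grasp–move–release
  task simulator with a spasticity coupling that delays myoelectric
  release.
- **Outcomes** (`bciloop.outcomes`): 19-item ARAT totals (0–57), release
  times from session logs, and the pooled two-sample t test comparing
  control modes, plus packaged score/time fixtures.

## Worked example

```bash
python examples/clinical_outcomes.py
```

prints

```
ARAT no_brace: 0 / 57
ARAT emg_myopro: 5 / 57
ARAT bci_myopro: 10 / 57

release times: BCI mean 6.45 s, EMG mean 12.90 s
pooled t = 2.11, df = 41, two-tailed p = 0.041
```

The ARAT (Action Research Arm Test) totals quantify upper-limb function
in each condition: 0 of 57 points without any device, 5 with the orthosis
under myoelectric (EMG threshold) control, 10 under BCI control.  The t
test compares hand release times — seconds from holding an object over
the target to dropping it — across 33 BCI and 10 myoelectric trials;
releases are about twice as fast under BCI control and the two-tailed
pooled-variance p rounds to 0.04.

The other example scripts each exercise one capability end to end:
`spike_pipeline.py` (thresholding → binning → leaky integration →
population activity), `trainingless_trigger.py` (band-power trigger hit
and false-fire rates), `decoder_calibration.py` (two-stage cursor
calibration and held-out closed-loop tracking),
`closed_loop_release_times.py` (myoelectric vs BCI release times under
simulated spasticity).

A thin CLI wraps the same functions:

```bash
bciloop simulate --config cfg.yaml --out session/
bciloop calibrate --seed 1 --out model.json
bciloop run --mode bci_filter --seed 1 --out out/
bciloop score out/session_bci_filter_1.jsonl
bciloop reproduce-trial
```

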