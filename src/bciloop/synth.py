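"""Seeded synthetic session generators.

No public recordings exist for the kind of single-participant intracortical
trial this package simulates, so every downstream stage is exercised on
synthetic sessions with the statistical structure the pipeline assumes:

* intent traces following cued movement scripts (rest / attempted hand
  action epochs);
* intent-modulated spike trains on a 256-channel array, realized as
  inhomogeneous Poisson processes, with optional rendering of the
  spike-band voltage (noise plus a stereotyped biphasic waveform);
* broadband LFP whose 100-500 Hz power sits at a resting baseline of
  0.5-3 V^2/Hz and rises above 10 V^2/Hz during attempted movement;
* 4-channel rectified-RMS EMG envelopes with post-stroke co-contraction
  (wrist flexor/extensor firing together) and flexor synergy (wrist
  flexors coupled to biceps);
* triangle-wave cursor-training target blocks and a synthetic
  "participant" whose firing follows the displayed cursor, for decoder
  calibration.

All generators are deterministic given (config, seed); there is no global
RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ContinuousRecording

#: Labels a cue epoch may carry.  ``rest`` maps to zero hand intent; every
#: other label is an attempted hand/wrist action with intent 1 by default.
EPOCH_LABELS = ("rest", "attempt_open", "attempt_close", "wrist_ext", "squeeze")


@dataclass
class IntentTrace:
    """Ground-truth movement intent on a uniform time grid.

    ``hand_intent`` is 0 at rest and 1 at maximal attempted hand action;
    ``elbow_intent`` is signed (flexion positive).  ``cursor_target_y`` is
    the normalized target position of a cursor-training block, or None.
    """

    times: np.ndarray
    hand_intent: np.ndarray
    elbow_intent: np.ndarray
    labels: np.ndarray
    cursor_target_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hand_intent = np.asarray(self.hand_intent, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.hand_intent < 0) | (self.hand_intent > 1)):
            raise ValueError("hand_intent must lie in [0, 1]")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)

    def is_movement(self) -> np.ndarray:
        """Boolean mask of samples belonging to non-rest epochs."""
        return np.asarray([lab != "rest" for lab in self.labels])


@dataclass
class NeuralSimConfig:
    """Parameters of the simulated microelectrode-array recording.

    256 channels with well-isolated units on 87 of them mirrors a typical
    four-array implant; ``tuning_gain`` is the firing-rate change per unit
    hand intent on a modulated channel (sign drawn per channel).  Band
    powers are one-sided PSD levels in V^2/Hz for the 100-500 Hz band.
    """

    n_channels: int = 256
    n_active_channels: int = 87
    baseline_rate: float = 10.0       # spikes/s
    tuning_gain: float = 20.0         # spikes/s per unit intent (magnitude)
    lfp_fs: float = 2000.0            # Hz
    spikeband_fs: float = 30000.0     # Hz
    rest_band_power: float = 1.5      # V^2/Hz, resting 100-500 Hz PSD
    move_band_power: float = 12.0     # V^2/Hz during attempted movement
    noise_sd: float = 20e-6           # volts, spike-band additive noise
    spike_snr: float = 10.0           # template peak / noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active_channels > self.n_channels:
            raise ValueError("n_active_channels must not exceed n_channels")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.rest_band_power >= self.move_band_power:
            raise ValueError("rest_band_power must be below move_band_power")

    def channel_gains(self) -> np.ndarray:
        """Signed per-channel tuning gains; zero off the active set.

        The active channels and the sign of each gain are drawn from the
        config seed, so the same config always describes the same array.
        """
        rng = np.random.default_rng(self.seed)
        gains = np.zeros(self.n_channels)
        active = rng.choice(self.n_channels, size=self.n_active_channels, replace=False)
        signs = rng.choice([-1.0, 1.0], size=self.n_active_channels)
        gains[active] = signs * self.tuning_gain
        return gains


@dataclass
class EmgSimConfig:
    """Parameters of the 4-channel surface-EMG envelope generator.

    Channels are fixed as (wrist_flexor, wrist_extensor, biceps, triceps).
    ``cocontraction_gain`` couples the wrist extensor to the flexor
    envelope (simultaneous agonist-antagonist contraction);
    ``synergy_gain`` couples the biceps to the flexor drive (abnormal
    flexor synergy).  Both are hallmarks of post-stroke spasticity.
    """

    baseline: float = 0.05            # volts, resting envelope level
    drive_gain: float = 0.5           # volts per unit intent
    synergy_gain: float = 0.5
    cocontraction_gain: float = 0.5
    noise_sd: float = 0.02            # volts
    dt: float = 0.1                   # seconds, envelope grid step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synergy_gain < 0 or self.cocontraction_gain < 0:
            raise ValueError("coupling gains must be non-negative")


EMG_CHANNELS = ("wrist_flexor", "wrist_extensor", "biceps", "triceps")


def make_intent_trace(
    protocol: Sequence,
    seed: int = 0,
    dt: float = 0.02,
) -> IntentTrace:
    """Build an intent trace from a session script.

    Parameters
    ----------
    protocol : sequence of (label, duration) or (label, duration, intent)
        Cue epochs in order.  ``label`` is one of :data:`EPOCH_LABELS`;
        ``duration`` is in seconds.  The optional third element overrides
        the default hand intent for the epoch (rest -> 0, movement -> 1).
    seed : int
        Reserved for stochastic protocol variants; the default script is
        deterministic but the argument keeps the call signature uniform.
    dt : float
        Grid step in seconds (<= 0.05).

    Returns
    -------
    IntentTrace covering the summed protocol duration.
    """
    if len(protocol) == 0:
        raise ValueError("empty session script")
    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must be in (0, 0.05] s")

    labels, intents, elbow = [], [], []
    for entry in protocol:
        label, duration = entry[0], float(entry[1])
        if label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {label!r}")
        if duration <= 0:
            raise ValueError("epoch durations must be positive")
        value = float(entry[2]) if len(entry) > 2 else (0.0 if label == "rest" else 1.0)
        n = int(round(duration / dt))
        labels.extend([label] * n)
        intents.extend([value] * n)
        elbow.extend([0.0] * n)

    times = np.arange(len(labels)) * dt
    return IntentTrace(
        times=times,
        hand_intent=np.array(intents),
        elbow_intent=np.array(elbow),
        labels=np.array(labels, dtype=object),
    )


def _biphasic_template(fs: float, amplitude: float, width: float = 1e-3) -> np.ndarray:
    """Stereotyped extracellular waveform: sharp negative lobe followed by
    a smaller positive rebound, ``width`` seconds long, peak ``-amplitude``."""
    n = max(int(round(width * fs)), 4)
    half = n // 2
    lobe = np.sin(np.pi * np.arange(half) / half)  # smooth unit half-wave
    wave = np.concatenate([-lobe, 0.4 * lobe])[:n]
    return amplitude * wave


def generate_spike_trains(
    intent: IntentTrace,
    cfg: NeuralSimConfig,
    render_voltage: bool = False,
    channels: Optional[Sequence[int]] = None,
):
    """Draw per-channel spike trains from intent-modulated Poisson rates.

    The rate on channel c is ``max(0, baseline_rate + gain_c * intent(t))``
    with signed gains on exactly ``n_active_channels`` channels, realized
    by thinning a homogeneous Poisson process.

    Parameters
    ----------
    intent : IntentTrace
    cfg : NeuralSimConfig
    render_voltage : bool
        If True, also render the spike-band voltage (additive Gaussian
        noise plus a biphasic template at each spike time) for the
        requested channels.  Rendering at 30 kHz is memory-hungry, so it
        is off by default and typically restricted to a channel subset.
    channels : sequence of int, optional
        Channels to simulate (default: all).

    Returns
    -------
    spikes : dict channel -> ndarray of spike times (s)
    recording : ContinuousRecording or None
        Rendered spike-band voltage (rows follow ``channels`` order).
    """
    if len(intent.times) == 0:
        raise ValueError("intent trace is empty")
    gains = cfg.channel_gains()
    if channels is None:
        channels = range(cfg.n_channels)
    channels = list(channels)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    t0, span = float(intent.times[0]), intent.duration
    spikes: dict[int, np.ndarray] = {}
    for c in channels:
        g = gains[c]
        rate_max = max(cfg.baseline_rate + max(g, 0.0), cfg.baseline_rate)
        if rate_max <= 0:
            spikes[c] = np.empty(0)
            continue
        n_cand = rng.poisson(rate_max * span)
        cand = np.sort(rng.uniform(t0, t0 + span, size=n_cand))
        inten = np.interp(cand, intent.times, intent.hand_intent)
        rate = np.maximum(cfg.baseline_rate + g * inten, 0.0)
        keep = rng.uniform(0, 1, size=n_cand) < rate / rate_max
        spikes[c] = cand[keep]

    recording = None
    if render_voltage:
        fs = cfg.spikeband_fs
        n_samp = int(round(span * fs))
        data = rng.normal(0.0, cfg.noise_sd, size=(len(channels), n_samp))
        template = _biphasic_template(fs, cfg.spike_snr * cfg.noise_sd)
        for row, c in enumerate(channels):
            for ts in spikes[c]:
                i0 = int(round((ts - t0) * fs))
                i1 = min(i0 + len(template), n_samp)
                if i0 < n_samp:
                    data[row, i0:i1] += template[: i1 - i0]
        recording = ContinuousRecording(data=data, fs=fs, start_time=t0)
    return spikes, recording


def generate_lfp(intent: IntentTrace, cfg: NeuralSimConfig, n_channels: int = 1) -> ContinuousRecording:
    """Render broadband LFP with piecewise-stationary flat PSD.

    Rest samples carry a one-sided PSD of ``rest_band_power`` V^2/Hz at
    every frequency; movement samples (hand intent >= 0.5) carry
    ``move_band_power``.  Because the spectrum is flat, the 100-500 Hz
    band power measured by the feature module equals the configured level
    in expectation.  A flat one-sided PSD P at sampling rate fs requires
    sample variance P * fs / 2.
    """
    if cfg.lfp_fs < 1000:
        raise ValueError("band exceeds Nyquist")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    fs = cfg.lfp_fs
    n_samp = int(round(intent.duration * fs))
    t = np.arange(n_samp) / fs + intent.times[0]
    inten = np.interp(t, intent.times, intent.hand_intent)
    power = np.where(inten >= 0.5, cfg.move_band_power, cfg.rest_band_power)
    sigma = np.sqrt(power * fs / 2.0)
    data = sigma * rng.normal(0.0, 1.0, size=(n_channels, n_samp))
    return ContinuousRecording(data=data, fs=fs, start_time=float(intent.times[0]))


def generate_emg(intent: IntentTrace, cfg: EmgSimConfig):
    """Generate 4-channel rectified-RMS EMG envelopes.

    The wrist flexor follows closing intent; the wrist extensor follows
    opening intent plus a co-contraction coupling to the flexor envelope;
    the biceps follows elbow flexion plus the abnormal flexor synergy;
    the triceps follows elbow extension.  Envelopes are clipped at zero
    (rectified RMS is non-negative).

    Returns
    -------
    times : ndarray (s)
    envelopes : ndarray, shape (4, n), rows ordered as EMG_CHANNELS
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    times = np.arange(intent.times[0], intent.times[0] + intent.duration, cfg.dt)
    inten = np.interp(times, intent.times, intent.hand_intent)
    labels_idx = np.minimum(
        np.searchsorted(intent.times, times, side="right") - 1, len(intent.times) - 1
    )
    labels = np.asarray(intent.labels, dtype=object)[labels_idx]
    closing = np.where([lab in ("attempt_close", "squeeze") for lab in labels], inten, 0.0)
    opening = np.where([lab in ("attempt_open", "wrist_ext") for lab in labels], inten, 0.0)
    elbow = np.interp(times, intent.times, intent.elbow_intent)

    noise = rng.normal(0.0, cfg.noise_sd, size=(4, len(times))) if cfg.noise_sd > 0 else np.zeros((4, len(times)))
    flexor = cfg.baseline + cfg.drive_gain * closing + noise[0]
    extensor = cfg.baseline + cfg.drive_gain * opening + cfg.cocontraction_gain * (flexor - cfg.baseline) + noise[1]
    biceps = cfg.baseline + cfg.drive_gain * np.maximum(elbow, 0) + cfg.synergy_gain * (flexor - cfg.baseline) + noise[2]
    triceps = cfg.baseline + cfg.drive_gain * np.maximum(-elbow, 0) + noise[3]
    envelopes = np.clip(np.vstack([flexor, extensor, biceps, triceps]), 0.0, None)
    return times, envelopes


def make_cursor_training_block(
    duration: float = 60.0, half_period: float = 5.0, dt: float = 0.02
):
    """Triangle-wave cursor target used for decoder calibration.

    The target starts at the top of the screen (y = 1) and takes
    ``half_period`` seconds to sweep to the bottom (y = 0) and back.

    Returns
    -------
    times : ndarray (s)
    y : ndarray, normalized screen position in [0, 1]
    """
    if duration <= 0 or half_period <= 0:
        raise ValueError("duration and half_period must be positive")
    times = np.arange(int(round(duration / dt))) * dt
    u = np.mod(times / half_period, 2.0)
    y = np.where(u <= 1.0, 1.0 - u, u - 1.0)
    return times, y


@dataclass
class SyntheticParticipant:
    """Neural source whose firing follows a displayed cursor target.

    Each of ``n_channels`` feature channels fires Poisson spike counts in
    ``bin_width`` bins at rate ``max(0, baseline_rate + gain_c * drive)``.
    The drive is the cursor target; when a prediction cursor is displayed
    (closed-loop retraining), the drive gains a coupling term
    ``feedback_coupling * feedback`` modelling the participant reacting to
    the prediction cursor.  Gains are drawn once from ``seed``.
    """

    n_channels: int = 40
    baseline_rate: float = 10.0
    gain_sd: float = 8.0
    bin_width: float = 0.2
    feedback_coupling: float = 0.0
    max_rate: float = 200.0      # physiological firing ceiling, spikes/s
    seed: int = 0
    gains: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 10]))
        self.gains = rng.normal(0.0, self.gain_sd, size=self.n_channels)

    def drive(self, target: np.ndarray, feedback: Optional[np.ndarray] = None) -> np.ndarray:
        d = np.asarray(target, dtype=float)
        if feedback is not None and self.feedback_coupling != 0.0:
            d = d + self.feedback_coupling * np.asarray(feedback, dtype=float)
        return d

    def respond(
        self,
        target: np.ndarray,
        feedback: Optional[np.ndarray] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Poisson spike counts (channels x bins) for a per-bin target."""
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
        d = self.drive(target, feedback)
        rate = np.clip(
            self.baseline_rate + self.gains[:, None] * d[None, :], 0.0, self.max_rate
        )
        return rng.poisson(rate * self.bin_width).astype(float)
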