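"""Motion-command generation and the simulated orthosis plant.

Two families of decision rules turn signals into discrete hand commands:

* EMG threshold modes (dual / open / close) — the powered orthosis
  compares rectified-RMS muscle envelopes against manually set
  thresholds;
* decoder discretization — a single position threshold (open/close) or a
  double threshold with a Hold band between.

A first-order plant integrates the commands into a hand aperture in
[0, 1] at a fixed motor rate, and :func:`run_closed_loop` wires a
synthetic participant, signal generation, decoding and the plant into a
grasp-move-release task, logging the events needed for release-time
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import Command, SessionLog
from .decoders import LinearFilterModel, two_stage_calibration
from .lfp import BandPowerConfig, TriggerConfig, periodogram_band_power, trainingless_trigger
from .synth import SyntheticParticipant


@dataclass
class EmgSample:
    """Rectified-RMS flexor/extensor envelope pair for one joint."""

    flexors: float
    extensors: float

    def __post_init__(self) -> None:
        if self.flexors < 0 or self.extensors < 0:
            raise ValueError("EMG envelopes are non-negative")


@dataclass
class EmgThresholds:
    flex_th: float = 0.3
    ext_th: float = 0.3

    def __post_init__(self) -> None:
        if self.flex_th <= 0 or self.ext_th <= 0:
            raise ValueError("EMG thresholds must be positive")


@dataclass
class DiscretizationConfig:
    """Position threshold(s) on the decoder output.

    Single-threshold rule uses ``at``; the double-threshold rule uses
    ``at1 < at2`` with a Hold band between them.
    """

    at: float = 0.5
    at1: float = 0.35
    at2: float = 0.65

    def __post_init__(self) -> None:
        if self.at1 >= self.at2:
            raise ValueError("at1 must be below at2")


def discretize_single_threshold(x_t: float, cfg: DiscretizationConfig) -> Command:
    """Extension (open) below the threshold, Flexion (close) at or above."""
    return Command.OPEN if x_t < cfg.at else Command.CLOSE


def discretize_double_threshold(x_t: float, cfg: DiscretizationConfig) -> Command:
    """Three-way rule with a Hold band: Extension below ``at1``, Hold in
    [at1, at2), Flexion at or above ``at2``."""
    if cfg.at1 >= cfg.at2:
        raise ValueError("at1 must be below at2")
    if x_t < cfg.at1:
        return Command.OPEN
    if x_t < cfg.at2:
        return Command.HOLD
    return Command.CLOSE


def emg_dual_mode(sample: EmgSample, th: EmgThresholds) -> Command:
    """Dual mode: both envelopes decide.

    Open requires quiet flexors and active extensors; Close the reverse;
    anything else (including co-contraction and exact threshold hits)
    holds.
    """
    if sample.flexors < th.flex_th and sample.extensors > th.ext_th:
        return Command.OPEN
    if sample.flexors > th.flex_th and sample.extensors < th.ext_th:
        return Command.CLOSE
    return Command.HOLD


def emg_open_mode(sample: EmgSample, th: EmgThresholds) -> Command:
    """Open mode: extensors alone decide; the default posture is closed.

    The boundary (envelope exactly at threshold) falls to the default
    posture branch.
    """
    return Command.OPEN if sample.extensors > th.ext_th else Command.CLOSE


def emg_close_mode(sample: EmgSample, th: EmgThresholds) -> Command:
    """Close mode: flexors alone decide; the default posture is open.

    This is the configuration used when residual wrist flexion is the
    only reliable voluntary signal: the hand stays open unless flexor
    activity exceeds the threshold.
    """
    return Command.CLOSE if sample.flexors > th.flex_th else Command.OPEN


@dataclass
class OrthosisState:
    """Simulated hand motor: aperture 1 = fully open, 0 = fully closed."""

    aperture: float = 1.0
    motor_rate: float = 2.0       # aperture units per second
    mode: str = "bci"

    def __post_init__(self) -> None:
        self.aperture = float(np.clip(self.aperture, 0.0, 1.0))


def orthosis_step(state: OrthosisState, cmd: Command, dt: float) -> OrthosisState:
    """Advance the plant one step: Open drives aperture toward 1, Close
    toward 0, Hold leaves it; travel is rate-limited and clamped."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    delta = state.motor_rate * dt
    if cmd is Command.OPEN:
        ap = state.aperture + delta
    elif cmd is Command.CLOSE:
        ap = state.aperture - delta
    else:
        ap = state.aperture
    return replace(state, aperture=float(np.clip(ap, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Closed-loop grasp-move-release task


@dataclass
class ScenarioConfig:
    """Grasp-move-release task script and plant/signal parameters.

    Each trial: the object is presented with the hand open; the
    participant closes onto it (grasp), transports it for a fixed time,
    arrives over the bin, then opens to drop it.  The release time is
    the interval from the over-bin event to the aperture crossing
    ``release_threshold``.

    ``spasticity`` enables the abnormal-tone coupling seen post-stroke:
    in myoelectric mode the wrist-flexor envelope stays elevated after a
    grasp and decays only slowly (time constant ``spasticity_tau``)
    while the participant attempts to open, so the motors fight the
    retained tone and release is delayed.
    """

    n_trials: int = 5
    motor_rate: float = 2.0
    grasp_threshold: float = 0.2     # aperture at which the object is held
    release_threshold: float = 0.7   # aperture at which the object drops
    transport_duration: float = 2.0  # seconds
    intertrial: float = 1.0          # seconds
    phase_timeout: float = 20.0      # safety cap per phase
    # myoelectric-pathway parameters
    emg_thresholds: EmgThresholds = field(default_factory=EmgThresholds)
    emg_baseline: float = 0.05
    emg_drive: float = 0.6
    emg_noise_sd: float = 0.03
    spasticity: bool = True
    spasticity_level: float = 0.55   # tone added to the flexor envelope
    spasticity_tau: float = 1.5      # seconds, tone decay during opening
    # BCI-filter pathway
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    # training-less pathway
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    rest_band_power: float = 1.5
    move_band_power: float = 12.0
    lfp_fs: float = 2000.0


_MODE_DT = {"oracle": 0.1, "myoelectric": 0.1, "bci_filter": 0.2, "bci_trainingless": 0.5}


class _MyoPathway:
    """Flexor-envelope generator with optional spastic tone retention."""

    def __init__(self, cfg: ScenarioConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.tone = 0.0

    def command(self, closing: bool, dt: float) -> Command:
        cfg = self.cfg
        if closing:
            if cfg.spasticity:
                self.tone = cfg.spasticity_level
            drive = cfg.emg_drive
        else:
            self.tone *= np.exp(-dt / cfg.spasticity_tau)
            drive = 0.0
        flexors = max(
            cfg.emg_baseline + drive + self.tone + self.rng.normal(0, cfg.emg_noise_sd),
            0.0,
        )
        return emg_close_mode(
            EmgSample(flexors=flexors, extensors=cfg.emg_baseline),
            cfg.emg_thresholds,
        )


class _FilterPathway:
    """Synthetic participant -> lagged counts -> linear filter -> rule 2."""

    def __init__(
        self,
        cfg: ScenarioConfig,
        participant: SyntheticParticipant,
        model: LinearFilterModel,
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.participant = participant
        self.model = model
        self.rng = rng
        self.history: list[np.ndarray] = []
        self.feedback = 0.5

    def command(self, closing: bool, dt: float) -> Command:
        target = 1.0 if closing else 0.0
        c_t = self.participant.respond(
            np.array([target]), feedback=np.array([self.feedback]), rng=self.rng
        )[:, 0]
        self.history.append(c_t)
        lags = self.model.lags
        if len(self.history) <= max(lags):
            return Command.HOLD  # warm-up: not enough history
        row = np.concatenate([self.history[-1 - lag] for lag in lags])
        x_t = float(row @ self.model.weights + self.model.intercept)
        self.feedback = x_t
        return discretize_double_threshold(x_t, self.cfg.discretization)


class _TraininglessPathway:
    """Rolling LFP buffer -> band power -> absolute-threshold trigger."""

    def __init__(self, cfg: ScenarioConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.band_cfg = BandPowerConfig()
        self.buffer = np.zeros(0)

    def command(self, closing: bool, dt: float) -> Command:
        cfg = self.cfg
        power = cfg.move_band_power if closing else cfg.rest_band_power
        n_new = int(round(dt * cfg.lfp_fs))
        sigma = np.sqrt(power * cfg.lfp_fs / 2.0)
        self.buffer = np.concatenate([self.buffer, sigma * self.rng.normal(size=n_new)])
        wlen = int(round(self.band_cfg.window * cfg.lfp_fs))
        self.buffer = self.buffer[-wlen:]
        if len(self.buffer) < wlen:
            return Command.OPEN
        _, band = periodogram_band_power(self.buffer, cfg.lfp_fs, self.band_cfg)
        return trainingless_trigger([band], cfg.trigger)[0]


class _OraclePathway:
    """Perfect decoder: the intended command, with no noise or delay."""

    def command(self, closing: bool, dt: float) -> Command:
        return Command.CLOSE if closing else Command.OPEN


def run_closed_loop(
    scenario: ScenarioConfig,
    mode: str,
    seed: int,
    participant: Optional[SyntheticParticipant] = None,
    model: Optional[LinearFilterModel] = None,
) -> SessionLog:
    """Simulate a seeded grasp-move-release session in one control mode.

    Parameters
    ----------
    mode : {"oracle", "myoelectric", "bci_filter", "bci_trainingless"}
    participant, model :
        For ``bci_filter``: the neural source and fitted filter.  If
        omitted, a default participant is created and calibrated with
        the two-stage cursor protocol under the session seed.

    Returns
    -------
    SessionLog with per-step records and task events (object_presented,
    grasped, over_bin, released).  Release events carry the exact
    within-step crossing time of the release threshold so that oracle
    release times match plant kinematics exactly.
    """
    if mode not in _MODE_DT:
        raise ValueError(f"unknown mode {mode!r}")
    dt = _MODE_DT[mode]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 30]))
    if mode == "oracle":
        pathway = _OraclePathway()
    elif mode == "myoelectric":
        pathway = _MyoPathway(scenario, rng)
    elif mode == "bci_trainingless":
        pathway = _TraininglessPathway(scenario, rng)
    else:
        if participant is None:
            participant = SyntheticParticipant(seed=seed)
        if model is None:
            model = two_stage_calibration(participant, seed=seed)
        pathway = _FilterPathway(scenario, participant, model, rng)

    log = SessionLog(mode=mode, seed=seed, meta={"dt": dt})
    state = OrthosisState(aperture=1.0, motor_rate=scenario.motor_rate, mode=mode)
    t = 0.0

    def step(closing: bool) -> None:
        nonlocal t, state
        cmd = pathway.command(closing, dt)
        prev = state.aperture
        state = orthosis_step(state, cmd, dt)
        t += dt
        log.log(t, cmd, state.aperture)
        step.last_crossing = None
        thr = scenario.release_threshold
        if prev < thr <= state.aperture:
            # exact in-step crossing time of the release threshold
            step.last_crossing = t - dt + (thr - prev) / scenario.motor_rate

    step.last_crossing = None

    for _ in range(scenario.n_trials):
        log.mark(t, "object_presented")
        deadline = t + scenario.phase_timeout
        while state.aperture > scenario.grasp_threshold and t < deadline:
            step(closing=True)
        log.mark(t, "grasped")
        transport_end = t + scenario.transport_duration
        while t < transport_end:
            step(closing=True)
        log.mark(t, "over_bin")
        deadline = t + scenario.phase_timeout
        released = False
        while state.aperture < scenario.release_threshold and t < deadline:
            step(closing=False)
            released = step.last_crossing is not None or released
        if step.last_crossing is not None:
            log.mark(step.last_crossing, "released")
        elif state.aperture >= scenario.release_threshold:
            log.mark(t, "released")
        else:
            log.mark(t, "release_timeout")
        rest_end = t + scenario.intertrial
        while t < rest_end:
            step(closing=False)
    return log
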