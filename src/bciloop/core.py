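"""Shared containers for the simulated BCI pipeline.

The pipeline passes three kinds of data between stages: continuous
multichannel voltage (spike-band or local field potential), binned
channel-by-time feature matrices (spike counts or band powers), and
discrete motion commands driving the simulated orthosis plant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Command(enum.Enum):
    """Discrete hand-motion command.

    ``OPEN`` corresponds to extension (hand opening), ``CLOSE`` to flexion
    (hand closing); ``HOLD`` leaves the motor where it is.
    """

    OPEN = "open"
    HOLD = "hold"
    CLOSE = "close"

    # clinical synonyms
    @property
    def is_extension(self) -> bool:
        return self is Command.OPEN

    @property
    def is_flexion(self) -> bool:
        return self is Command.CLOSE


#: Aliases matching the extension/flexion vocabulary of orthosis control.
EXTENSION = Command.OPEN
FLEXION = Command.CLOSE
HOLD = Command.HOLD


@dataclass
class ContinuousRecording:
    """Multichannel sampled voltage.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in volts.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds.
    units : str
        Physical units of ``data`` (always volts in this package).
    """

    data: np.ndarray
    fs: float
    start_time: float = 0.0
    units: str = "volts"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class SessionLog:
    """Timestamped record of one simulated closed-loop session.

    ``records`` holds one entry per control update: (time, command,
    aperture).  ``events`` holds task markers: (time, event-name) where
    names include ``object_presented``, ``grasped``, ``over_bin`` and
    ``released``.
    """

    mode: str
    seed: int
    records: list = field(default_factory=list)
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def log(self, t: float, command: Command, aperture: float) -> None:
        self.records.append((float(t), command.value, float(aperture)))

    def mark(self, t: float, event: str) -> None:
        self.events.append((float(t), str(event)))

    def to_jsonl(self) -> str:
        import json

        lines = [json.dumps({"meta": {"mode": self.mode, "seed": self.seed, **self.meta}})]
        for t, cmd, ap in self.records:
            lines.append(json.dumps({"t": t, "command": cmd, "aperture": ap}))
        for t, ev in self.events:
            lines.append(json.dumps({"t": t, "event": ev}))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "SessionLog":
        import json

        records, events, meta = [], [], {}
        for line in text.strip().splitlines():
            obj = json.loads(line)
            if "meta" in obj:
                meta = obj["meta"]
            elif "event" in obj:
                events.append((obj["t"], obj["event"]))
            else:
                records.append((obj["t"], obj["command"], obj["aperture"]))
        log = cls(mode=meta.get("mode", "unknown"), seed=meta.get("seed", -1))
        log.records, log.events = records, events
        log.meta = {k: v for k, v in meta.items() if k not in ("mode", "seed")}
        return log
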