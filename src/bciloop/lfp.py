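"""High-gamma LFP band-power features and the training-less trigger.

The feature is the average one-sided periodogram density in the
100-500 Hz band, summarized in non-overlapping 50-Hz frequency bins,
computed over 1-second rolling windows with 50% overlap (one value every
500 ms).  The training-less control mode ranks channels by how strongly
this feature is modulated between rest and attempted movement, averages
the top channels, and closes the hand whenever the averaged power
exceeds an absolute threshold (10 V^2/Hz against a resting baseline of
0.5-3 V^2/Hz).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import Command, ContinuousRecording
from .synth import IntentTrace


@dataclass
class BandPowerConfig:
    """Band and windowing parameters of the feature stream."""

    band_lo: float = 100.0       # Hz
    band_hi: float = 500.0       # Hz
    bin_width_hz: float = 50.0
    window: float = 1.0          # seconds
    overlap_frac: float = 0.5
    update: float = 0.5          # seconds; must equal window*(1-overlap)

    def __post_init__(self) -> None:
        if self.band_hi <= self.band_lo:
            raise ValueError("band_hi must exceed band_lo")
        n = (self.band_hi - self.band_lo) / self.bin_width_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("band width must be divisible by bin_width_hz")
        if abs(self.update - self.window * (1 - self.overlap_frac)) > 1e-9:
            raise ValueError("update must equal window * (1 - overlap_frac)")

    @property
    def n_bins(self) -> int:
        return int(round((self.band_hi - self.band_lo) / self.bin_width_hz))

    def bin_edges(self) -> np.ndarray:
        return self.band_lo + np.arange(self.n_bins + 1) * self.bin_width_hz


@dataclass
class FeatureStream:
    """Per-channel band power (V^2/Hz) at each 500-ms update.

    ``times`` are window-end times: the value at t summarizes samples in
    (t - window, t] — the stream is causal.
    """

    times: np.ndarray
    values: np.ndarray           # channels x windows
    config: BandPowerConfig

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("band power must be non-negative")

    def mean_over(self, channels: Sequence[int]) -> np.ndarray:
        """Average the stream over a channel subset (scalar per window)."""
        return self.values[list(channels), :].mean(axis=0)

    def to_csv(self) -> str:
        c = self.config
        buf = io.StringIO()
        buf.write(
            f"# band={c.band_lo}-{c.band_hi} bin_width_hz={c.bin_width_hz} "
            f"window={c.window} overlap={c.overlap_frac}\n"
        )
        buf.write("time," + ",".join(f"ch{i}" for i in range(self.values.shape[0])) + "\n")
        for j, t in enumerate(self.times):
            buf.write(f"{t}," + ",".join(repr(float(v)) for v in self.values[:, j]) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "FeatureStream":
        lines = text.strip().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        lo, hi = map(float, header["band"].split("-"))
        cfg = BandPowerConfig(
            band_lo=lo,
            band_hi=hi,
            bin_width_hz=float(header["bin_width_hz"]),
            window=float(header["window"]),
            overlap_frac=float(header["overlap"]),
            update=float(header["window"]) * (1 - float(header["overlap"])),
        )
        times, rows = [], []
        for ln in lines[2:]:
            parts = ln.split(",")
            times.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
        return cls(times=np.asarray(times), values=np.asarray(rows).T, config=cfg)


@dataclass
class TriggerConfig:
    """Absolute-threshold hand-close trigger."""

    threshold: float = 10.0      # V^2/Hz
    n_channels: int = 20         # most-neuromodulated channels averaged

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def periodogram_band_power(
    window_samples: np.ndarray, fs: float, cfg: BandPowerConfig | None = None
):
    """One-sided rectangular-taper periodogram summarized in 50-Hz bins.

    Parameters
    ----------
    window_samples : ndarray
        Exactly one analysis window of samples (length = window * fs).
    fs : float
        Sampling rate; must satisfy fs >= 2 * band_hi.

    Returns
    -------
    bin_values : ndarray, length cfg.n_bins
        Mean PSD density (V^2/Hz) over each 50-Hz frequency bin.
    band_average : float
        Mean of the bin values — the scalar feature.
    """
    cfg = cfg or BandPowerConfig()
    x = np.asarray(window_samples, dtype=float)
    if fs < 2 * cfg.band_hi:
        raise ValueError("band exceeds Nyquist")
    expected = int(round(cfg.window * fs))
    if len(x) < expected:
        raise ValueError(f"window has {len(x)} samples, need {expected}")
    freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    edges = cfg.bin_edges()
    bin_values = np.empty(cfg.n_bins)
    for i in range(cfg.n_bins):
        sel = (freqs >= edges[i]) & (freqs < edges[i + 1])
        bin_values[i] = psd[sel].mean() if sel.any() else 0.0
    return bin_values, float(bin_values.mean())


def rolling_feature_stream(
    recording: ContinuousRecording, cfg: BandPowerConfig | None = None
) -> FeatureStream:
    """Band-power feature stream over 1-s windows stepped every 500 ms.

    Windows are end-aligned (causal): the value reported at time t uses
    samples in (t - window, t].  A recording of duration D yields
    floor((D - window) / update) + 1 windows.  Note that streams computed
    on two concatenated recordings differ from concatenated streams at
    the seam — windows straddling the boundary exist only in the former.
    """
    cfg = cfg or BandPowerConfig()
    fs = recording.fs
    wlen = int(round(cfg.window * fs))
    step = int(round(cfg.update * fs))
    n = recording.n_samples
    if n < wlen:
        raise ValueError("recording shorter than one analysis window")
    starts = np.arange(0, n - wlen + 1, step)
    values = np.empty((recording.n_channels, len(starts)))
    for c in range(recording.n_channels):
        for j, s in enumerate(starts):
            _, values[c, j] = periodogram_band_power(
                recording.data[c, s : s + wlen], fs, cfg
            )
    times = recording.start_time + (starts + wlen) / fs
    return FeatureStream(times=times, values=values, config=cfg)


def window_labels(stream: FeatureStream, intent: IntentTrace) -> np.ndarray:
    """Boolean movement mask per stream window (majority of samples)."""
    move = intent.is_movement().astype(float)
    out = np.empty(len(stream.times), dtype=bool)
    for j, t in enumerate(stream.times):
        lo, hi = t - stream.config.window, t
        sel = (intent.times > lo) & (intent.times <= hi)
        out[j] = move[sel].mean() > 0.5 if sel.any() else False
    return out


def rank_neuromodulated_channels(
    stream: FeatureStream, labels, n: int
) -> list[int]:
    """Channels ranked by movement-vs-rest band-power modulation.

    The score is the absolute standardized mean difference of window
    values between movement and rest windows (pooled SD).  Ties break by
    ascending channel index.

    Parameters
    ----------
    labels : IntentTrace or boolean array
        Either the ground-truth intent trace (windows are classified by
        majority vote, see :func:`window_labels`) or a pre-computed
        per-window movement mask.
    n : int
        Number of channels to return.
    """
    if isinstance(labels, IntentTrace):
        labels = window_labels(stream, labels)
    mask = np.asarray(labels, dtype=bool)
    if mask.all() or (~mask).all():
        raise ValueError("need both movement and rest windows to rank channels")
    if n == 0:
        return []
    move, rest = stream.values[:, mask], stream.values[:, ~mask]
    pooled = np.sqrt((move.var(axis=1, ddof=1) + rest.var(axis=1, ddof=1)) / 2.0)
    pooled = np.where(pooled > 0, pooled, np.inf)  # identical channels score 0
    score = np.abs(move.mean(axis=1) - rest.mean(axis=1)) / pooled
    score = np.where(np.isfinite(score), score, 0.0)
    order = np.lexsort((np.arange(len(score)), -score))
    return [int(i) for i in order[:n]]


def trainingless_trigger(
    mean_power: np.ndarray, cfg: TriggerConfig | None = None
) -> list[Command]:
    """Threshold trigger: Close when mean band power exceeds threshold.

    Strict inequality: a value exactly at threshold leaves the hand
    opening (the resting default).
    """
    cfg = cfg or TriggerConfig()
    return [
        Command.CLOSE if v > cfg.threshold else Command.OPEN
        for v in np.asarray(mean_power, dtype=float)
    ]
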