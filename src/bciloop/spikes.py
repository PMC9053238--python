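"""Spike-band processing: thresholding, binning, leaky integration.

Spikes are detected as threshold crossings (multiunit activity, no
sorting) with the threshold set per channel as a multiplier of the
signal's root-mean-square amplitude.  Counts are binned in 200-ms
windows, smoothed with a first-order leaky integrator and optionally
max-normalized and summed across channels to give a population-activity
trace.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class SpikeThresholdConfig:
    """RMS-multiplier thresholding.

    ``rms_multiplier`` is signed: the conventional extracellular setting
    is negative (spikes are negative-going).  ``lockout`` suppresses
    re-triggering for its duration after each detected spike.
    """

    rms_multiplier: float = -4.5
    lockout: float = 0.001  # seconds

    def __post_init__(self) -> None:
        if self.rms_multiplier == 0:
            raise ValueError("rms_multiplier must be non-zero")
        if self.lockout < 0:
            raise ValueError("lockout must be non-negative")


@dataclass
class BinnedCounts:
    """Spike counts on a contiguous half-open bin grid [t, t+width)."""

    counts: np.ndarray          # channels x bins, non-negative integers
    bin_width: float = 0.2
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_bins) * self.bin_width

    def to_csv(self) -> str:
        """Bins as rows, channels as columns; bin width in the header."""
        buf = io.StringIO()
        buf.write(f"# bin_width={self.bin_width} start_time={self.start_time}\n")
        buf.write("bin," + ",".join(f"ch{c}" for c in range(self.counts.shape[0])) + "\n")
        for b in range(self.n_bins):
            buf.write(f"{b}," + ",".join(str(int(v)) for v in self.counts[:, b]) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "BinnedCounts":
        lines = text.strip().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        rows = [list(map(int, ln.split(",")[1:])) for ln in lines[2:]]
        return cls(
            counts=np.array(rows).T,
            bin_width=float(header["bin_width"]),
            start_time=float(header["start_time"]),
        )


@dataclass
class IntegratedRates:
    """Leaky-integrated (and optionally max-normalized) spike counts."""

    values: np.ndarray
    tau: float
    bin_width: float = 0.2
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("integrated rates must be non-negative")


def compute_rms_threshold(voltage: np.ndarray, cfg: SpikeThresholdConfig, fs: float = None) -> float:
    """Per-channel detection threshold: ``rms_multiplier * RMS(voltage)``.

    ``fs`` is only used to enforce that at least one second of signal is
    supplied; pass None to skip the check (e.g. for unit fixtures).
    """
    v = np.asarray(voltage, dtype=float)
    if fs is not None and len(v) < fs:
        raise ValueError("need at least 1 s of signal to estimate RMS")
    rms = float(np.sqrt(np.mean(v**2)))
    if rms == 0.0:
        warnings.warn("all-zero signal: threshold is 0", stacklevel=2)
        return 0.0
    return cfg.rms_multiplier * rms


def detect_spikes(
    voltage: np.ndarray, threshold: float, fs: float, lockout: float = 0.001
) -> np.ndarray:
    """Threshold-crossing spike times (seconds from the first sample).

    For a negative threshold a spike is logged at the first sample of
    each negative-going crossing; for a positive threshold, at each
    positive-going crossing.  Crossings within ``lockout`` of the
    previous spike are suppressed.  Returned times are strictly
    increasing.
    """
    if threshold == 0:
        raise ValueError("threshold must be non-zero")
    v = np.asarray(voltage, dtype=float)
    if threshold < 0:
        below = v < threshold
    else:
        below = v > threshold
    # first sample of each excursion
    onsets = np.flatnonzero(below & ~np.r_[False, below[:-1]])
    times = onsets / fs
    if lockout > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= lockout:
                kept.append(t)
        times = np.asarray(kept)
    return times


def bin_spike_counts(
    spikes: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    bin_width: float = 0.2,
    span: tuple[float, float] | None = None,
) -> BinnedCounts:
    """Histogram spike times into contiguous half-open bins [t, t+w).

    ``span`` is (start, stop); it must cover every spike.  The total
    count is conserved.
    """
    if isinstance(spikes, Mapping):
        keys = sorted(spikes)
        trains = [np.asarray(spikes[k], dtype=float) for k in keys]
    else:
        trains = [np.asarray(s, dtype=float) for s in spikes]
    if span is None:
        hi = max((s.max() for s in trains if len(s)), default=0.0)
        span = (0.0, hi + bin_width)
    t0, t1 = span
    for s in trains:
        if len(s) and (s.min() < t0 or s.max() >= t1):
            raise ValueError("spike time outside binning span")
    n_bins = int(np.ceil((t1 - t0) / bin_width - 1e-12))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.zeros((len(trains), n_bins), dtype=int)
    for c, s in enumerate(trains):
        if len(s):
            idx = np.floor((s - t0) / bin_width).astype(int)
            idx = np.clip(idx, 0, n_bins - 1)  # guard float edge of final bin
            np.add.at(counts[c], idx, 1)
    return BinnedCounts(counts=counts, bin_width=bin_width, start_time=t0)


def leaky_integrate(counts: BinnedCounts, tau: float = 0.5) -> IntegratedRates:
    """First-order leaky integration of binned counts.

    r_t = r_{t-1} * exp(-width/tau) + c_t, with r_{-1} = 0.  A constant
    input c settles at c / (1 - exp(-width/tau)).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    decay = np.exp(-counts.bin_width / tau)
    c = counts.counts.astype(float)
    out = np.empty_like(c)
    prev = np.zeros(c.shape[0])
    for b in range(c.shape[1]):
        prev = prev * decay + c[:, b]
        out[:, b] = prev
    return IntegratedRates(values=out, tau=tau, bin_width=counts.bin_width)


def normalize_rates(rates: IntegratedRates) -> IntegratedRates:
    """Divide each channel by its maximum over the displayed span.

    Channels that never fire are left at zero.
    """
    peak = rates.values.max(axis=1, keepdims=True)
    safe = np.where(peak > 0, peak, 1.0)
    return IntegratedRates(
        values=rates.values / safe,
        tau=rates.tau,
        bin_width=rates.bin_width,
        normalized=True,
    )


def population_sum(rates: IntegratedRates, normalize: bool = False) -> np.ndarray:
    """Per-bin sum of integrated rates across channels.

    With ``normalize`` each channel is first divided by its own maximum
    (the convention used for displaying cross-array activity).
    """
    if rates.values.size == 0:
        raise ValueError("empty rate matrix")
    r = normalize_rates(rates) if normalize else rates
    return r.values.sum(axis=0)
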