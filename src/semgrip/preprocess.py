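"""Raw signals to feature streams.

The only EMG feature is the mean absolute value (MAV): for channel j with
samples f_j(i*T1), the stream value at step k is

    g_j(kT) = 1/(2N) * sum_{i=-N+1..N} |f_j(kT + i*T1)|,

a 2N-sample (100 ms at 2 kHz, N=100) window advanced in steps of T = 50 ms,
i.e. 20 overlapping instances per second and 2400 per 120 s run.  Windows at
the stream edges are truncated to the available samples and averaged over the
actual count, so the instance count is exactly floor(duration/T).

The accelerometer stream is reduced to a per-step summed absolute difference
across the six hand-sensor channels, on a decimated grid of every 7th ACC
sample (7/148.1 s ~ 47 ms, ~21.1 steps/s); its run median drives onset
detection in the labelling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .io import ChannelSeries, RunBundle

__all__ = [
    "MavStream",
    "AccSummary",
    "ChannelStats",
    "mav_from_samples",
    "compute_mav",
    "bandpass",
    "fit_channel_stats",
    "apply_zscore",
    "invert_zscore",
    "summarize_acc",
]

MAV_STEP_S = 0.05  # T
MAV_HALF_WIDTH = 100  # N, samples at 2 kHz
ACC_DECIMATE = 7  # ACC summary step, samples


@dataclass
class MavStream:
    """Time-indexed sequence of 8-channel MAV instances."""

    times: np.ndarray  # (m,) seconds, arithmetic with step `step`
    values: np.ndarray  # (m, 8), non-negative before normalisation
    step: float = MAV_STEP_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 8:
            raise ValueError(f"instances must have 8 channels, got {self.values.shape[1]}")
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class AccSummary:
    """Summed-absolute-difference ACC statistic and its run median."""

    times: np.ndarray  # (m,) seconds
    stat: np.ndarray  # (m,) >= 0, g units
    median: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stat = np.asarray(self.stat, dtype=float)
        if self.times.shape != self.stat.shape:
            raise ValueError("times and stat must have equal length")


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and (population) standard deviation of training MAVs."""

    mean: np.ndarray  # (8,)
    std: np.ndarray  # (8,)


def mav_from_samples(x: np.ndarray, step: int, half_width: int) -> np.ndarray:
    """MAV stream of one channel: windows [k*step - N, k*step + N) of |x|.

    Sample indices follow the f(i*T1), i = 1, 2, ... convention, so window k
    covers 1-based samples k*step - N + 1 .. k*step + N.  Windows are clipped
    to the signal and averaged over the actual sample count.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m = n // step
    if m < 2:
        raise ValueError(f"signal too short for MAV: {n} samples at step {step}")
    c = np.concatenate([[0.0], np.cumsum(np.abs(x))])
    k = np.arange(1, m + 1)
    lo = np.clip(k * step - half_width, 0, n)
    hi = np.clip(k * step + half_width, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def compute_mav(
    bundle: RunBundle, step_s: float = MAV_STEP_S, half_width: int = MAV_HALF_WIDTH
) -> MavStream:
    """MAV feature stream of a run's eight EMG channels."""
    step = int(round(step_s * bundle.emg_rate))
    cols = [mav_from_samples(c.values, step, half_width) for c in bundle.emg]
    values = np.stack(cols, axis=1)
    times = step_s * np.arange(1, values.shape[0] + 1)
    return MavStream(times=times, values=values, step=step_s)


def bandpass(
    series: ChannelSeries,
    low: float = 20.0,
    high: float = 450.0,
    order: int = 4,
    enabled: bool = True,
) -> ChannelSeries:
    """Zero-phase flat-passband (Butterworth) band-pass filter.

    The acquisition hardware already applies a 20-450 Hz band-pass, so for
    pre-filtered (or simulated) input ``enabled=False`` returns the series
    unchanged.
    """
    if not enabled:
        return series
    if series.rate <= 2 * high:
        raise ValueError(
            f"sample rate {series.rate} Hz too low for a {high} Hz band edge"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=series.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, series.values)
    return ChannelSeries(series.sensor_id, series.kind, series.rate, filtered, series.start_time)


def fit_channel_stats(streams: MavStream | Iterable[MavStream]) -> ChannelStats:
    """Per-channel mean/std of training MAV values (population convention)."""
    if isinstance(streams, MavStream):
        streams = [streams]
    values = np.concatenate([s.values for s in streams], axis=0)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 instances per channel to fit stats")
    mean = values.mean(axis=0)
    std = values.std(axis=0)  # ddof=0
    if np.any(std == 0):
        bad = [j + 1 for j in np.flatnonzero(std == 0)]
        raise ValueError(f"degenerate (constant) channel(s): {bad}")
    return ChannelStats(mean=mean, std=std)


def apply_zscore(stream: MavStream, stats: ChannelStats) -> MavStream:
    """Standardise each channel with *training* statistics."""
    return replace(stream, values=(stream.values - stats.mean) / stats.std)


def invert_zscore(stream: MavStream, stats: ChannelStats) -> MavStream:
    return replace(stream, values=stream.values * stats.std + stats.mean)


def summarize_acc(bundle: RunBundle, decimate: int = ACC_DECIMATE) -> AccSummary:
    """Summed |ACC(t+1) - ACC(t)| across hand channels on a decimated grid.

    Differences are taken between every ``decimate``-th sample and summed over
    all ACC channels (absolute values, so opposite-axis changes do not
    cancel); each statistic is stamped with the later sample's time.
    """
    if not bundle.acc:
        raise ValueError("run has no ACC channels")
    v = bundle.acc_matrix[:, ::decimate]
    t = bundle.acc[0].times[::decimate]
    if v.shape[1] < 2:
        raise ValueError("too few ACC samples to difference")
    stat = np.abs(np.diff(v, axis=1)).sum(axis=0)
    return AccSummary(times=t[1:], stat=stat, median=float(np.median(stat)))
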