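"""Sinusoidal defocus signals, zero-crossing statistics, and the five
temporal decision strategies.

A presentation epoch is 300 ms sampled at 1 ms; the epoch's start time is
drawn uniformly over one signal period, so the phase of the defocus cycle at
stimulus onset is unpredictable, as in unsynchronized viewing.

Strategies (applied to the 300-sample defocus series):

* ``average`` - average the 300 defocused images (all samples, equal weight);
* ``least``   - split the epoch into six 50-ms bins, average within bins, and
  use the bin whose mean absolute defocus is smallest;
* ``early``   - average the first 100 ms;
* ``late``    - average the last 100 ms;
* ``mixed``   - draw one of the four strategies per trial, equiprobably.

Because optical filtering is linear, averaging the defocused images is
equivalent to filtering once with the average of the per-sample OTFs; the
strategies are therefore expressed as index masks over the epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "DefocusSignal",
    "EpochConfig",
    "Strategy",
    "defocus_series",
    "zero_crossing_probability",
    "zero_crossing_interval",
    "strategy_sample_indices",
    "least_defocus_bin",
]


@dataclass(frozen=True)
class DefocusSignal:
    """d(t) = dc_offset + amplitude * sin(2 pi f t + phase), in diopters."""

    amplitude_d: float
    frequency_hz: float
    phase_rad: float = 0.0
    dc_offset_d: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_d < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    def value(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        out = self.dc_offset_d + self.amplitude_d * np.sin(
            2.0 * math.pi * self.frequency_hz * t + self.phase_rad
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class EpochConfig:
    """Presentation epoch timing (durations in milliseconds)."""

    duration_ms: int = 300
    dt_ms: int = 1
    bin_ms: int = 50
    window_ms: int = 100

    def __post_init__(self) -> None:
        if self.duration_ms % self.bin_ms:
            raise ValueError("epoch duration must divide into whole bins")
        if self.window_ms > self.duration_ms:
            raise ValueError("early/late window cannot exceed the epoch")

    @property
    def n_samples(self) -> int:
        return self.duration_ms // self.dt_ms

    @property
    def n_bins(self) -> int:
        return self.duration_ms // self.bin_ms

    @property
    def samples_per_bin(self) -> int:
        return self.bin_ms // self.dt_ms

    @property
    def window_samples(self) -> int:
        return self.window_ms // self.dt_ms


class Strategy(str, Enum):
    AVERAGE = "average"
    LEAST = "least"
    EARLY = "early"
    LATE = "late"
    MIXED = "mixed"


def defocus_series(
    sig: DefocusSignal, t0_ms: float, epoch: EpochConfig | None = None
) -> np.ndarray:
    """Defocus (D) sampled at t0 + k*dt for the whole epoch (300 samples)."""
    epoch = epoch or EpochConfig()
    t_ms = t0_ms + np.arange(epoch.n_samples) * epoch.dt_ms
    return np.asarray(sig.value(t_ms * 1e-3))


def zero_crossing_interval(frequency_hz: float) -> float:
    """Time between successive zero-defocus instants of a zero-mean sinusoid,
    in seconds: half the period (250 ms at 2 Hz)."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return 0.5 / frequency_hz


def zero_crossing_probability(
    frequency_hz: float,
    duration_s: float,
    amplitude_d: float = 1.0,
    dc_offset_d: float = 0.0,
) -> float:
    """Probability that a uniformly placed window contains a zero-defocus
    instant of ``dc + A sin(2 pi f t)``.

    For a zero-mean signal the zeros are evenly spaced every half-period and
    the probability is min(1, 2 f d).  With a nonzero offset |dc| < A the two
    zeros per period split the cycle into unequal gaps g and T - g, and the
    window covers a zero with probability (min(g, d) + min(T - g, d)) / T.
    With |dc| >= A (and A > 0 or a pure offset) no zeros exist.
    """
    if frequency_hz <= 0 or duration_s <= 0:
        raise ValueError("frequency and duration must be positive")
    if abs(dc_offset_d) >= amplitude_d:
        return 0.0 if (dc_offset_d != 0.0 or amplitude_d == 0.0) else 1.0
    T = 1.0 / frequency_hz
    if dc_offset_d == 0.0:
        return min(1.0, 2.0 * frequency_hz * duration_s)
    # zeros where sin = -dc/A: two per period, separated by gap g
    s = -dc_offset_d / amplitude_d
    t1 = math.asin(s) / (2.0 * math.pi) * T
    t2 = (math.pi - math.asin(s)) / (2.0 * math.pi) * T
    g = t2 - t1
    return min(1.0, (min(g, duration_s) + min(T - g, duration_s)) / T)


def least_defocus_bin(series: np.ndarray, epoch: EpochConfig | None = None) -> int:
    """Index of the 50-ms bin with the smallest mean absolute defocus."""
    epoch = epoch or EpochConfig()
    bins = np.abs(series).reshape(epoch.n_bins, epoch.samples_per_bin).mean(axis=1)
    return int(np.argmin(bins))


def strategy_sample_indices(
    series: np.ndarray,
    strategy: Strategy | str,
    epoch: EpochConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Epoch sample indices whose defocused images are averaged for matching."""
    epoch = epoch or EpochConfig()
    strategy = Strategy(strategy)
    if strategy is Strategy.MIXED:
        if rng is None:
            raise ValueError("the mixed strategy needs a random generator")
        pick = (Strategy.AVERAGE, Strategy.LEAST, Strategy.EARLY, Strategy.LATE)[
            int(rng.integers(4))
        ]
        return strategy_sample_indices(series, pick, epoch, rng)
    if strategy is Strategy.AVERAGE:
        return np.arange(epoch.n_samples)
    if strategy is Strategy.EARLY:
        return np.arange(epoch.window_samples)
    if strategy is Strategy.LATE:
        return np.arange(epoch.n_samples - epoch.window_samples, epoch.n_samples)
    b = least_defocus_bin(series, epoch)
    return np.arange(b * epoch.samples_per_bin, (b + 1) * epoch.samples_per_bin)
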