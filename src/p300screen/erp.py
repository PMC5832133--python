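"""Coherent averaging and the group-level ERP statistics.

Target and nontarget epochs are averaged pointwise across epochs and
channels into one waveform per condition; the P300 is read off as the
highest peak inside the 150-450 ms window, target/nontarget differences are
tested per subject with a two-sided Mann-Whitney U over the windowed
samples, and peak magnitudes are contrasted across subjects with a paired
Wilcoxon signed-rank test.

Pooling the per-sample amplitudes of two smooth averages treats
autocorrelated values as exchangeable; this is a deliberate simplification
of the procedure being reproduced (see docs/methods.md) rather than a
recommended test for band-limited data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from p300screen.errors import ConfigurationError
from p300screen.preprocessing import Epoch

#: Default analysis window (ms after flash onset) where the P300 appears.
DEFAULT_WINDOW_MS = (150.0, 450.0)


@dataclass
class CoherentAverage:
    """Channel-combined pointwise mean of event-locked epochs."""

    waveform: np.ndarray
    n_epochs: int
    condition: str
    sample_rate: float = 512.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ConfigurationError("n_epochs must be >= 1")
        self.waveform = np.asarray(self.waveform, dtype=float)


@dataclass(frozen=True)
class PeakResult:
    latency_ms: float
    amplitude: float
    window_ms: tuple[float, float]


def window_indices(
    window_ms: tuple[float, float], sample_rate: float, n_samples: int
) -> np.ndarray:
    """Sample indices whose onset-relative time lies inside the window
    (inclusive ends); 77..230 for 150-450 ms at 512 Hz."""
    lo_ms, hi_ms = window_ms
    if hi_ms <= lo_ms:
        raise ConfigurationError("window must have positive length")
    lo = int(math.ceil(lo_ms * sample_rate / 1000.0 - 1e-9))
    hi = int(math.floor(hi_ms * sample_rate / 1000.0 + 1e-9))
    lo, hi = max(lo, 0), min(hi, n_samples - 1)
    if hi < lo:
        raise ConfigurationError(f"window {window_ms} ms outside the epoch span")
    return np.arange(lo, hi + 1)


def coherent_average(epochs: list[Epoch], condition: str) -> CoherentAverage:
    """Pointwise mean over all epochs and all channels of each epoch."""
    if not epochs:
        raise ConfigurationError("cannot average an empty epoch list")
    stacked = np.stack([e.samples for e in epochs])  # epochs x channels x time
    return CoherentAverage(
        waveform=stacked.mean(axis=(0, 1)),
        n_epochs=len(epochs),
        condition=condition,
    )


def peak_in_window(
    avg: CoherentAverage, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> PeakResult:
    """Highest amplitude inside the window; ties go to the earlier latency."""
    idx = window_indices(window_ms, avg.sample_rate, len(avg.waveform))
    segment = avg.waveform[idx]
    best = int(np.argmax(segment))  # argmax returns the first maximum
    sample = int(idx[best])
    return PeakResult(
        latency_ms=sample / avg.sample_rate * 1000.0,
        amplitude=float(segment[best]),
        window_ms=window_ms,
    )


def compare_windows(
    target_avg: CoherentAverage,
    nontarget_avg: CoherentAverage,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U over the windowed per-sample amplitudes.

    Returns (U, p).  The two waveforms must have equal length.
    """
    if len(target_avg.waveform) != len(nontarget_avg.waveform):
        raise ConfigurationError("averages must have the same length")
    idx = window_indices(window_ms, target_avg.sample_rate, len(target_avg.waveform))
    if idx.size < 2:
        raise ConfigurationError("window spans fewer than 2 samples")
    x = target_avg.waveform[idx]
    y = nontarget_avg.waveform[idx]
    if np.ptp(np.concatenate([x, y])) == 0.0:
        # fully tied pooled sample: no evidence of any difference
        return float(x.size * y.size / 2.0), 1.0
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Bonferroni correction across the comparisons of one run, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def group_peak_test(
    target_peaks: np.ndarray | list[float],
    nontarget_peaks: np.ndarray | list[float],
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank on per-subject peak magnitudes.

    Returns (W, p) where W is the smaller signed-rank sum, so W = 0 when
    every target peak exceeds its nontarget pair.  All-zero differences are
    degenerate and reported as (0.0, 1.0).
    """
    t = np.asarray(target_peaks, dtype=float)
    nt = np.asarray(nontarget_peaks, dtype=float)
    if t.shape != nt.shape:
        raise ConfigurationError("paired samples must have equal length")
    if t.size < 5:
        raise ConfigurationError("need at least 5 pairs")
    if np.allclose(t, nt):
        return 0.0, 1.0
    res = scipy.stats.wilcoxon(t, nt, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
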