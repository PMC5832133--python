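"""Filtering, epoching, standardization, and featurization.

The chain mirrors the offline analysis of the paradigm: a 40th-order
1.5-10 Hz linear-phase FIR bandpass (Chebyshev window), flash-locked epochs
of 307 samples (600 ms at 512 Hz), per-channel linear detrend and z-scoring,
then featurization by concatenating the channels and decimating the
concatenated vector by two, giving d = 1228 features for 8 channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from p300screen.errors import ConfigurationError, DataFormatError
from p300screen.recording import Recording
from p300screen.sequencer import StimulusEvent

#: Epoch length in seconds from flash onset (no pre-stimulus baseline).
EPOCH_SPAN_S = 0.600


def epoch_n_samples(sample_rate: float, span_s: float = EPOCH_SPAN_S) -> int:
    """Samples per epoch: floor(span * rate); 307 at 512 Hz."""
    return int(math.floor(span_s * sample_rate))


def feature_dim(n_channels: int, n_epoch_samples: int) -> int:
    """Length of the decimated concatenation: ceil(C * S / 2)."""
    return (n_channels * n_epoch_samples + 1) // 2


@dataclass
class Epoch:
    """One flash-locked epoch: channels x samples, with its source event."""

    samples: np.ndarray
    event: StimulusEvent
    standardized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("epoch samples must be channels x time")


@dataclass
class FeatureVector:
    """Flattened, decimated representation of one epoch with its labels."""

    values: np.ndarray
    marker_id: int
    trial: int
    repetition: int
    label: int  # +1 target, -1 nontarget

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.label not in (-1, 1):
            raise ConfigurationError("label must be -1 or +1")


def design_bandpass(
    order: int = 40,
    band: tuple[float, float] = (1.5, 10.0),
    window_attenuation_db: float = 60.0,
    sample_rate: float = 512.0,
) -> np.ndarray:
    """Linear-phase FIR bandpass of ``order`` (order+1 taps), Chebyshev window.

    The realized response of so short a filter is gentle at the low edge;
    the design is reproduced as stated rather than sharpened.
    """
    lo, hi = band
    if not 0.0 < lo < hi < sample_rate / 2.0:
        raise ConfigurationError(f"band {band} must lie inside (0, {sample_rate / 2})")
    return scipy.signal.firwin(
        order + 1,
        [lo, hi],
        window=("chebwin", window_attenuation_db),
        pass_zero=False,
        fs=sample_rate,
    )


def apply_filter(recording: Recording, coefficients: np.ndarray) -> Recording:
    """Convolve each channel and compensate the (order/2)-sample group delay,
    so event onsets remain aligned to the same sample indices."""
    coefficients = np.asarray(coefficients, dtype=float)
    delay = (len(coefficients) - 1) // 2
    n = recording.n_samples
    filtered = np.empty_like(recording.samples)
    for ch in range(recording.n_channels):
        full = np.convolve(recording.samples[ch], coefficients, mode="full")
        filtered[ch] = full[delay : delay + n]
    return Recording(
        samples=filtered,
        sample_rate=recording.sample_rate,
        channel_names=recording.channel_names,
        schedule=recording.schedule,
    )


def extract_epochs(
    recording: Recording, events: list[StimulusEvent]
) -> list[Epoch]:
    """One epoch per flash event, starting at the flash onset sample."""
    n_epoch = epoch_n_samples(recording.sample_rate)
    epochs: list[Epoch] = []
    for event in events:
        if event.event_type != "flash":
            continue
        start = int(round(event.onset * recording.sample_rate))
        stop = start + n_epoch
        if start < 0 or stop > recording.n_samples:
            raise DataFormatError(
                f"epoch for flash at {event.onset:.3f} s (marker {event.marker_id}, "
                f"repetition {event.repetition}, trial {event.trial}) exceeds the "
                f"recording bounds ({recording.n_samples} samples)"
            )
        epochs.append(Epoch(recording.samples[:, start:stop].copy(), event))
    return epochs


def standardize_epoch(epoch: Epoch) -> Epoch:
    """Remove each channel's best-fit line, then z-score to mean 0, variance 1."""
    detrended = scipy.signal.detrend(epoch.samples, axis=1, type="linear")
    std = detrended.std(axis=1)
    bad = np.flatnonzero(std < 1e-12)
    if bad.size:
        ch = int(bad[0])
        raise DataFormatError(
            f"channel {ch} has zero variance after detrend for flash at "
            f"{epoch.event.onset:.3f} s (marker {epoch.event.marker_id})"
        )
    z = (detrended - detrended.mean(axis=1, keepdims=True)) / std[:, None]
    return Epoch(z, epoch.event, standardized=True)


def featurize(epoch: Epoch) -> FeatureVector:
    """Concatenate channels (channel-major) and keep every second element.

    Decimation is plain subsampling of the concatenated vector starting at
    index 0 — the signal is already band-limited to 10 Hz, and this rule is
    what yields d = 1228 for 8 channels x 307 samples.
    """
    if not epoch.standardized:
        raise ConfigurationError("featurize requires a standardized epoch")
    values = epoch.samples.ravel(order="C")[::2]
    e = epoch.event
    return FeatureVector(
        values=values,
        marker_id=e.marker_id,
        trial=e.trial,
        repetition=e.repetition,
        label=1 if e.is_target else -1,
    )
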