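"""Synthetic multichannel EEG with event-locked ERP templates.

The generator stands in for real recordings so every downstream stage is
testable end to end.  Background activity is 1/f^alpha Gaussian noise per
channel; at each flash onset a parametric ERP template (a sum of Gaussian
pulses such as an N200 negativity and a P300 positivity) is added, scaled
by a per-channel gain and latency-jittered per event.  Amplitudes are
conventions, not claims about any particular dataset: per-epoch
standardization downstream makes only the ERP-to-noise ratio meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from p300screen.errors import ConfigurationError
from p300screen.recording import DEFAULT_CHANNELS, Recording
from p300screen.sequencer import SessionSchedule

#: Epoch span (seconds) the recording must cover past the last event.
EPOCH_SPAN_S = 0.600


@dataclass(frozen=True)
class ERPComponent:
    """One Gaussian pulse of an ERP template.

    amplitude is signed (negative for N-waves) in microvolts; latency is the
    pulse center and width the Gaussian sigma, both in milliseconds.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigurationError("component width must be positive")


#: Minimal target morphology: N200-like negativity then P300-like positivity.
#: The 310 ms P300 latency matches the median reported for this paradigm.
DEFAULT_TARGET_COMPONENTS = (
    ERPComponent("N200", latency_ms=200.0, width_ms=25.0, amplitude_uv=-2.5),
    ERPComponent("P300", latency_ms=310.0, width_ms=45.0, amplitude_uv=5.0),
)

#: Centro-parietal dominance: the P300 is largest at Pz in this montage.
DEFAULT_CHANNEL_GAINS = (0.6, 0.55, 0.8, 0.55, 0.75, 1.0, 0.75, 0.5)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject.

    noise_scale is the broadband RMS (microvolts) of the 1/f^alpha
    background; latency_jitter_ms shifts the whole template per event,
    making single-trial detection nontrivial without burying the average.
    """

    target_components: tuple[ERPComponent, ...] = DEFAULT_TARGET_COMPONENTS
    nontarget_components: tuple[ERPComponent, ...] = ()
    noise_scale: float = 14.0
    noise_exponent: float = 1.0
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    latency_jitter_ms: float = 20.0
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 60.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        if len(self.channel_gains) != 8:
            raise ConfigurationError("channel_gains must have 8 entries")
        if self.latency_jitter_ms < 0:
            raise ConfigurationError("latency_jitter_ms must be >= 0")


def _gaussian_sum(
    components: tuple[ERPComponent, ...],
    n_samples: int,
    sample_rate: float,
    latency_shift_ms: float = 0.0,
) -> np.ndarray:
    """Sum of Gaussian pulses; tolerates latencies outside the window."""
    t_ms = np.arange(n_samples) / sample_rate * 1000.0
    wave = np.zeros(n_samples)
    for c in components:
        center = c.latency_ms + latency_shift_ms
        wave += c.amplitude_uv * np.exp(-((t_ms - center) ** 2) / (2.0 * c.width_ms**2))
    return wave


def make_erp_template(
    components: tuple[ERPComponent, ...] | list[ERPComponent],
    n_samples: int,
    sample_rate: float,
) -> np.ndarray:
    """Clean single-channel ERP template: sum of the components' Gaussians."""
    components = tuple(components)
    span_ms = n_samples / sample_rate * 1000.0
    for c in components:
        if not 0.0 <= c.latency_ms < span_ms:
            raise ConfigurationError(
                f"component {c.name!r} latency {c.latency_ms} ms outside epoch span "
                f"[0, {span_ms:.1f}) ms"
            )
    return _gaussian_sum(components, n_samples, sample_rate)


def powerlaw_noise(
    n_samples: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectrum proportional to 1/f^exponent.

    Spectral shaping of white noise in the frequency domain; exponent 0
    returns plain white noise.  The DC bin is zeroed.
    """
    white = rng.standard_normal(n_samples)
    if exponent == 0.0:
        return white / max(white.std(), np.finfo(float).tiny)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n=n_samples)
    return shaped / max(shaped.std(), np.finfo(float).tiny)


def generate_recording(
    schedule: SessionSchedule,
    profile: SubjectProfile,
    rng: np.random.Generator,
    sample_rate: float = 512.0,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
) -> Recording:
    """Simulate the session: shaped background plus event-locked templates.

    Deterministic given the rng state: noise is drawn channel by channel,
    then one latency jitter per flash event in onset order.
    """
    if len(channel_names) != len(profile.channel_gains):
        raise ConfigurationError("channel count must match profile channel_gains")
    n_samples = int(math.ceil((schedule.total_duration + EPOCH_SPAN_S) * sample_rate)) + 1
    n_channels = len(channel_names)
    samples = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        noise = powerlaw_noise(n_samples, profile.noise_exponent, rng)
        samples[ch] = profile.noise_scale * noise
    if profile.line_noise_amplitude > 0.0:
        t = np.arange(n_samples) / sample_rate
        line = profile.line_noise_amplitude * np.sin(
            2.0 * np.pi * profile.line_noise_freq * t
        )
        samples += line  # common-mode hum across all channels

    n_template = int(math.floor(EPOCH_SPAN_S * sample_rate))
    gains = np.asarray(profile.channel_gains)
    for event in schedule.flash_events():
        components = (
            profile.target_components if event.is_target else profile.nontarget_components
        )
        if not components:
            continue
        jitter = (
            rng.normal(0.0, profile.latency_jitter_ms)
            if profile.latency_jitter_ms > 0
            else 0.0
        )
        template = _gaussian_sum(components, n_template, sample_rate, jitter)
        start = int(round(event.onset * sample_rate))
        samples[:, start : start + n_template] += gains[:, None] * template[None, :]
    return Recording(
        samples=samples,
        sample_rate=sample_rate,
        channel_names=tuple(channel_names),
        schedule=schedule,
    )
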