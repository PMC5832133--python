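"""Container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from p300screen.errors import ConfigurationError
from p300screen.sequencer import SessionSchedule

#: Standard 8-electrode montage of the paradigm (10-20 positions, A1-A2 referenced).
DEFAULT_CHANNELS = ("Fz", "C3", "Cz", "C4", "P3", "Pz", "P4", "Oz")


@dataclass
class Recording:
    """Multichannel EEG: channels x time matrix in microvolts.

    ``schedule`` aligns stimulus events to samples; sample k of any channel
    was acquired at k / sample_rate seconds from session start.
    """

    samples: np.ndarray
    sample_rate: float = 512.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    schedule: SessionSchedule | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate
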