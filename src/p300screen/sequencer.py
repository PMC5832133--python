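"""Stimulus sequencing and session scheduling for the scenario-screen paradigm.

The paradigm is a single-marker oddball: each *trial* flashes all markers
exactly once in random order, a *repetition* is the run of trials performed
to make one selection, and a *block* groups several repetitions between
start/end cues and baseline recordings.  The sequencer enforces the two
constraints that distinguish the engine from a naive shuffler: interstimulus
intervals are drawn pseudorandomly from a small discrete set, and the same
marker never flashes twice in a row — including across trial and repetition
boundaries within a block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from p300screen.errors import ConfigurationError, InfeasibleDesignError

#: Default seed for module-level reproducibility when a caller supplies none.
DEFAULT_SEED = 20180214

EVENT_TYPES = (
    "flash",
    "target_cue",
    "block_start",
    "block_end",
    "baseline_start",
    "baseline_end",
)


@dataclass(frozen=True)
class TimingConfig:
    """Timing parameters of one stimulation session.

    Durations are in seconds.  Defaults describe the evaluated paradigm:
    twelve markers flashed for 125 ms with interstimulus intervals drawn
    uniformly from six values between 120 and 220 ms, 0.5 s between trials,
    ten trials per repetition, four blocks of 3/5/6/6 repetitions, a 5 s
    target cue (five blinks at 1 Hz) before each repetition, 5 s between
    repetitions, 5 s start/end cues and 20 s baselines around each block.
    """

    n_markers: int = 12
    flash_duration: float = 0.125
    isi_values: tuple[float, ...] = (0.12, 0.14, 0.16, 0.18, 0.20, 0.22)
    iti: float = 0.5
    target_cue_blinks: int = 5
    blink_rate: float = 1.0
    inter_repetition_interval: float = 5.0
    trials_per_repetition: int = 10
    block_reps: tuple[int, ...] = (3, 5, 6, 6)
    start_end_cue: float = 5.0
    baseline: float = 20.0

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ConfigurationError("n_markers must be >= 2")
        if len(self.isi_values) == 0:
            raise ConfigurationError("isi_values must be nonempty")
        durations = (
            self.flash_duration,
            self.iti,
            self.blink_rate,
            self.inter_repetition_interval,
            self.start_end_cue,
            self.baseline,
            *self.isi_values,
        )
        if any(d <= 0 for d in durations):
            raise ConfigurationError("all durations and rates must be positive")
        if self.target_cue_blinks < 1 or self.trials_per_repetition < 1:
            raise ConfigurationError("counts must be positive")
        if len(self.block_reps) == 0 or any(k < 1 for k in self.block_reps):
            raise ConfigurationError("block_reps must be positive counts")

    @property
    def mean_isi(self) -> float:
        return float(np.mean(self.isi_values))

    @property
    def target_cue_duration(self) -> float:
        """Cue length in seconds: number of blinks at the blink rate."""
        return self.target_cue_blinks / self.blink_rate

    @property
    def n_repetitions(self) -> int:
        return int(sum(self.block_reps))


@dataclass(frozen=True)
class StimulusEvent:
    """One timed event of a session.  Indices are -1 where not applicable."""

    onset: float
    duration: float
    marker_id: int
    event_type: str
    block: int = -1
    repetition: int = -1
    trial: int = -1
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ConfigurationError("event onset must be >= 0")
        if self.event_type not in EVENT_TYPES:
            raise ConfigurationError(f"unknown event_type {self.event_type!r}")


@dataclass(frozen=True)
class TrialSequence:
    """Flashing order of one trial: a permutation of all marker ids."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ConfigurationError("trial order must be a permutation of marker ids")


@dataclass
class SessionSchedule:
    """The complete timed event stream of one recording session."""

    events: list[StimulusEvent]
    timing: TimingConfig
    targets: list[int]
    total_duration: float

    def flash_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.event_type == "flash"]

    def flash_stream(self) -> np.ndarray:
        """Marker ids of all flashes in onset order."""
        return np.array([e.marker_id for e in self.flash_events()], dtype=int)


def draw_isi(timing: TimingConfig, rng: np.random.Generator) -> float:
    """Draw one interstimulus interval, i.i.d. uniform over the configured set."""
    if len(timing.isi_values) == 0:
        raise ConfigurationError("isi_values must be nonempty")
    return float(rng.choice(np.asarray(timing.isi_values, dtype=float)))


def generate_trial(
    timing: TimingConfig,
    previous_last_marker: int | None,
    rng: np.random.Generator,
) -> TrialSequence:
    """Random permutation of all markers whose first flash avoids a repeat.

    ``previous_last_marker`` is the marker that flashed last before this
    trial (possibly in the previous trial or repetition); the permutation is
    resampled until its first element differs, which leaves the law uniform
    over the admissible permutations.
    """
    n = timing.n_markers
    if n < 2 and previous_last_marker is not None:
        raise ConfigurationError("need n_markers >= 2 to avoid consecutive repeats")
    while True:
        order = rng.permutation(n)
        if previous_last_marker is None or order[0] != previous_last_marker:
            return TrialSequence(tuple(int(m) for m in order))


def generate_repetition(
    target: int,
    timing: TimingConfig,
    previous_last_marker: int | None,
    rng: np.random.Generator,
) -> list[TrialSequence]:
    """The trials of one repetition, chained so no marker flashes twice in a row."""
    if not 0 <= target < timing.n_markers:
        raise ConfigurationError(f"target {target} outside [0, {timing.n_markers})")
    trials: list[TrialSequence] = []
    last = previous_last_marker
    for _ in range(timing.trials_per_repetition):
        trial = generate_trial(timing, last, rng)
        trials.append(trial)
        last = trial.order[-1]
    return trials


def assign_targets(
    n_repetitions: int, timing: TimingConfig, rng: np.random.Generator
) -> list[int]:
    """Shuffled target list where every marker is the target once or twice."""
    n = timing.n_markers
    if not n <= n_repetitions <= 2 * n:
        raise InfeasibleDesignError(
            f"n_repetitions={n_repetitions} must lie in [{n}, {2 * n}] "
            "so each marker is targeted once or twice"
        )
    doubled = rng.choice(n, size=n_repetitions - n, replace=False)
    targets = np.concatenate([np.arange(n), doubled])
    rng.shuffle(targets)
    return [int(t) for t in targets]


def build_session(
    timing: TimingConfig, rng: np.random.Generator
) -> SessionSchedule:
    """Assemble the full session: blocks of repetitions with cues and baselines.

    Per block: a start cue, a baseline, then k repetitions each preceded by a
    target cue; consecutive repetitions are separated by the
    inter-repetition interval (none after the block's last), an end cue and
    a closing baseline follow.  Within a repetition, trials are separated by
    the intertrial interval; every flash occupies flash_duration followed by
    a drawn interstimulus interval.  Inter-block rest is not part of the
    schedule, so total_duration is stimulation time only.
    """
    targets = assign_targets(timing.n_repetitions, timing, rng)
    events: list[StimulusEvent] = []
    t = 0.0
    rep_index = 0
    for block, k in enumerate(timing.block_reps):
        events.append(StimulusEvent(t, timing.start_end_cue, -1, "block_start", block))
        t += timing.start_end_cue
        events.append(StimulusEvent(t, timing.baseline, -1, "baseline_start", block))
        t += timing.baseline
        last_marker: int | None = None  # the no-repeat chain resets per block
        for r in range(k):
            target = targets[rep_index]
            events.append(
                StimulusEvent(
                    t,
                    timing.target_cue_duration,
                    target,
                    "target_cue",
                    block,
                    rep_index,
                    is_target=True,
                )
            )
            t += timing.target_cue_duration
            trials = generate_repetition(target, timing, last_marker, rng)
            for trial_idx, trial in enumerate(trials):
                for marker in trial.order:
                    events.append(
                        StimulusEvent(
                            t,
                            timing.flash_duration,
                            marker,
                            "flash",
                            block,
                            rep_index,
                            trial_idx,
                            is_target=(marker == target),
                        )
                    )
                    t += timing.flash_duration + draw_isi(timing, rng)
                if trial_idx < len(trials) - 1:
                    t += timing.iti
            last_marker = trials[-1].order[-1]
            rep_index += 1
            if r < k - 1:
                t += timing.inter_repetition_interval
        events.append(StimulusEvent(t, timing.start_end_cue, -1, "block_end", block))
        t += timing.start_end_cue
        events.append(StimulusEvent(t, timing.baseline, -1, "baseline_end", block))
        t += timing.baseline
    return SessionSchedule(events=events, timing=timing, targets=targets, total_duration=t)


def selection_time(l_trials: int, timing: TimingConfig) -> float:
    """Average time to make one selection by accumulating ``l_trials`` trials.

    Every flash costs the stimulus duration plus the mean interstimulus
    interval, and the l trials are separated by l-1 intertrial intervals:
    n_markers * l * (SD + mean ISI) + (l - 1) * ITI.
    """
    if l_trials < 1:
        raise ConfigurationError("l_trials must be >= 1")
    return (
        timing.n_markers * l_trials * (timing.flash_duration + timing.mean_isi)
        + (l_trials - 1) * timing.iti
    )


def expected_session_duration(timing: TimingConfig) -> float:
    """Analytic expectation of SessionSchedule.total_duration, in seconds."""
    per_rep = timing.target_cue_duration + selection_time(
        timing.trials_per_repetition, timing
    )
    fixed_per_block = 2 * (timing.start_end_cue + timing.baseline)
    inter_rep = sum(k - 1 for k in timing.block_reps) * timing.inter_repetition_interval
    return (
        len(timing.block_reps) * fixed_per_block
        + timing.n_repetitions * per_rep
        + inter_rep
    )
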