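"""Shared fixtures: seeded rngs, a fast miniature paradigm, and the
session-scoped 20-subject default-condition study used by the statistical
property tests."""

from __future__ import annotations

import numpy as np
import pytest

from p300screen import pipeline
from p300screen.config import EvaluationConfig, RunConfig
from p300screen.sequencer import DEFAULT_SEED, TimingConfig
from p300screen.synthetic import SubjectProfile


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(DEFAULT_SEED)


@pytest.fixture
def timing() -> TimingConfig:
    return TimingConfig()


@pytest.fixture(scope="session")
def small_config(tmp_path_factory) -> RunConfig:
    """Miniature paradigm (6 markers, 2 blocks, 5 trials/repetition) for
    fast end-to-end runs; the subject profile keeps the default SNR."""
    return RunConfig(
        timing=TimingConfig(
            n_markers=6, block_reps=(3, 4), trials_per_repetition=5
        ),
        evaluation=EvaluationConfig(l_values=(1, 2, 3, 4, 5), n_eval_reps=3),
        n_subjects=2,
        output_dir=str(tmp_path_factory.mktemp("runs")),
    )


@pytest.fixture(scope="session")
def study() -> tuple[RunConfig, list[pipeline.SubjectResult]]:
    """Twenty synthetic subjects through the full default pipeline.

    This is the package's reference simulated study: default timing
    (4 blocks of 3/5/6/6 repetitions), default subject profile, training on
    the 8 early analysis repetitions and evaluation on the held-out 9.
    """
    config = RunConfig(n_subjects=20)
    results = [pipeline.run_subject(config, s) for s in range(config.n_subjects)]
    return config, results
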