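"""Shared fixtures: small synthetic recordings and sample sets."""

import numpy as np
import pytest

from copnet import (
    CopRecording,
    SampleSet,
    TaskSpec,
    easy_params,
    hard_params,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_recordings():
    """Three short deterministic recordings, one per level.

    Sized so a (n_in=20, stride=10) windowing yields 9 windows per
    subject — enough for small train/test splits with a gap.
    """
    gen = np.random.default_rng(7)
    recs = []
    for level, scale in (("H", 0.5), ("M", 1.0), ("N", 2.0)):
        T = 100
        recs.append(
            CopRecording(
                subject_id=f"{level}#1",
                level=level,
                x=scale * gen.standard_normal(T),
                y=scale * gen.standard_normal(T),
                fs=100.0,
            )
        )
    return recs


@pytest.fixture
def toy_task():
    return TaskSpec("toy", ("H#1", "M#1", "N#1"), n_train=9, n_test=6)


@pytest.fixture(scope="session")
def short_easy_recordings():
    """Easy-regime six-subject dataset, shortened for unit tests.

    60 s at 100 Hz gives 59 windows per subject at the default stride —
    enough for small tasks, cheap to simulate.
    """
    return simulate_dataset(easy_params(seed=7, duration=60.0))


@pytest.fixture(scope="session")
def short_hard_recordings():
    return simulate_dataset(hard_params(seed=7, duration=60.0))


@pytest.fixture
def small_sample_set(rng):
    """Balanced 30-sample set of [2, 40] windows with level-scaled noise."""
    gen = np.random.default_rng(99)
    samples, labels, sids = [], [], []
    for label, scale in ((0, 0.5), (1, 1.0), (2, 2.0)):
        for _ in range(10):
            samples.append(scale * gen.standard_normal((2, 40)))
            labels.append(label)
            sids.append(f"{'HMN'[label]}#1")
    return SampleSet(np.stack(samples), np.array(labels), np.array(sids, dtype=object))
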