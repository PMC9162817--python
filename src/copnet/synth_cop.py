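"""Synthetic postural-sway generator.

Emulates a six-subject stabilometry study — two subjects at each of three
balance-control levels (H: high-level athlete, M: medium-level athlete,
N: normal person) — so the full classification pipeline can be exercised
without access to force-platform data.

Each COP channel follows a discretized Ornstein–Uhlenbeck (OU) process,

    c[t+1] = c[t] - theta * c[t] * dt + sigma_eff * sqrt(dt) * eps[t],

with an additive slow sinusoidal drift. Mean reversion (theta) mimics the
corrective action of postural control; the noise intensity sigma encodes
the level: better balance means smaller sway, so sigma_H < sigma_M <
sigma_N. A multiplicative per-subject jitter on sigma produces
between-subject variation within a level. The stationary standard
deviation of a drift-free channel is sigma / sqrt(2 * theta), which is the
calibration handle used by the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from .cop_data import LEVELS, CopRecording

__all__ = ["SwayParams", "easy_params", "hard_params", "simulate_subject", "simulate_dataset"]


@dataclass(frozen=True)
class SwayParams:
    """Parameters of the OU + drift sway model.

    theta          mean-reversion rate (1/s)
    sigma          per-level noise intensity (units/sqrt(s)); must be
                   ordered sigma[H] < sigma[M] < sigma[N]
    drift_amp      amplitude of the slow sinusoidal drift (units)
    drift_freq     drift frequency (Hz)
    subject_jitter multiplicative spread of sigma across subjects of one
                   level (fraction; sigma_eff = sigma * (1 + jitter * u),
                   u fixed per subject in [-1, 1])
    fs             sampling rate (Hz)
    duration       recording length (s); long enough by default for any
                   standard task at 50%-overlap windowing
    seed           master seed; every subject derives its own substreams
    """

    theta: float = 1.0
    sigma: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.6, "M": 1.0, "N": 1.6}
    )
    drift_amp: float = 0.3
    drift_freq: float = 0.1
    subject_jitter: float = 0.15
    fs: float = 100.0
    duration: float = 620.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        s = self.sigma
        if set(s) != set(LEVELS):
            raise ValueError(f"sigma must map exactly the levels {LEVELS}")
        if not s["H"] < s["M"] < s["N"]:
            raise ValueError("sigma must be ordered H < M < N (better balance, smaller sway)")
        if any(v < 0 for v in s.values()):
            raise ValueError("sigma values must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.fs))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @staticmethod
    def from_json(text: str) -> "SwayParams":
        return SwayParams(**json.loads(text))


def easy_params(seed: int = 0, **overrides) -> SwayParams:
    """Widely spaced per-level sigmas: classes are clearly separable."""
    return SwayParams(seed=seed, **overrides)


def hard_params(seed: int = 0, **overrides) -> SwayParams:
    """Narrow sigma spread (0.9 / 1.0 / 1.1): classes overlap strongly."""
    overrides.setdefault("sigma", {"H": 0.9, "M": 1.0, "N": 1.1})
    return SwayParams(seed=seed, **overrides)


def _subject_rngs(params: SwayParams, level: str, subject_index: int):
    """Independent, reproducible substreams for one subject.

    The jitter draw uses its own stream so that changing duration or fs
    never changes a subject's effective sigma.
    """
    key = (LEVELS.index(level), subject_index)
    noise_ss = np.random.SeedSequence(params.seed, spawn_key=(*key, 0))
    jitter_ss = np.random.SeedSequence(params.seed, spawn_key=(*key, 1))
    return np.random.default_rng(noise_ss), np.random.default_rng(jitter_ss)


def simulate_subject(
    params: SwayParams, level: str, subject_index: int
) -> CopRecording:
    """Simulate one subject's two-channel recording.

    Both channels share sigma_eff but use independent noise streams and
    independent drift phases. Euler–Maruyama discretization with
    dt = 1/fs and c_0 = 0; fully reproducible from
    (seed, level, subject_index).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    noise_rng, jitter_rng = _subject_rngs(params, level, subject_index)
    u = jitter_rng.uniform(-1.0, 1.0)
    sigma_eff = params.sigma[level] * (1.0 + params.subject_jitter * u)

    dt = 1.0 / params.fs
    T = params.n_steps
    a = 1.0 - params.theta * dt
    g = sigma_eff * np.sqrt(dt)
    t = np.arange(T) * dt

    channels = []
    for _ in range(2):
        eps = noise_rng.standard_normal(T)
        # c[t] = a*c[t-1] + g*eps[t-1], c[0] = 0  (one-pole recursion in C)
        driven = lfilter([g], [1.0, -a], eps)
        c = np.concatenate(([0.0], driven[:-1]))
        phase = noise_rng.uniform(0.0, 2.0 * np.pi)
        drift = params.drift_amp * np.sin(2.0 * np.pi * params.drift_freq * t + phase)
        channels.append(c + drift)

    return CopRecording(
        subject_id=f"{level}#{subject_index}",
        level=level,
        x=channels[0],
        y=channels[1],
        fs=params.fs,
    )


def simulate_dataset(params: SwayParams) -> list[CopRecording]:
    """Simulate the full six-subject dataset (two subjects per level)."""
    return [
        simulate_subject(params, level, idx)
        for level in LEVELS
        for idx in (1, 2)
    ]
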