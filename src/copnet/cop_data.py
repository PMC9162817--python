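"""Data model and I/O for center-of-pressure (COP) recordings.

A recording is a two-channel displacement time series — anteroposterior (x)
and mediolateral (y) sway sampled by a force platform, 100 Hz by default.
Recordings are windowed into fixed-length samples of shape ``[2, n_in]``
and assembled into the balanced train/test tasks used by the classifiers.

Label encoding is fixed: H -> 0, M -> 1, N -> 2 (high-level athlete,
medium-level athlete, normal person). Window coordinates are 0-based and
half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_TO_LABEL",
    "LABEL_TO_LEVEL",
    "CopDataError",
    "ParseError",
    "InsufficientDataError",
    "CopRecording",
    "SampleSet",
    "TaskSpec",
    "STANDARD_TASKS",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "window_recording",
    "build_task",
    "standardize",
]

LEVELS = ("H", "M", "N")
LEVEL_TO_LABEL = {"H": 0, "M": 1, "N": 2}
LABEL_TO_LEVEL = {v: k for k, v in LEVEL_TO_LABEL.items()}


class CopDataError(ValueError):
    """Base class for recording/sample-set errors."""


class ParseError(CopDataError):
    """A recording file contains a malformed or non-finite value."""


class InsufficientDataError(CopDataError):
    """A recording is too short to supply the requested windows."""


@dataclass
class CopRecording:
    """One subject's two-channel COP time series with its level label."""

    subject_id: str
    level: str
    x: np.ndarray
    y: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.level not in LEVELS:
            raise CopDataError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise CopDataError("channels must be 1D series")
        if self.x.size != self.y.size:
            raise CopDataError(
                f"channel lengths differ: x has {self.x.size}, y has {self.y.size}"
            )
        if self.fs <= 0:
            raise CopDataError("sampling rate must be positive")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise CopDataError("channel values must be finite")

    @property
    def n_steps(self) -> int:
        return int(self.x.size)

    @property
    def label(self) -> int:
        return LEVEL_TO_LABEL[self.level]

    def channels(self) -> np.ndarray:
        """Stack the two channels as a ``[2, T]`` array (x first)."""
        return np.stack([self.x, self.y])


@dataclass
class SampleSet:
    """A stack of ``[2, n_in]`` windows with class labels and provenance."""

    samples: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.samples.ndim != 3 or self.samples.shape[1] != 2:
            raise CopDataError(
                f"samples must have shape [n, 2, n_in], got {self.samples.shape}"
            )
        n = self.samples.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise CopDataError("samples, labels and subject_ids must align")
        if n and not np.all(np.isin(self.labels, list(LABEL_TO_LEVEL))):
            raise CopDataError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_in(self) -> int:
        return int(self.samples.shape[2])

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(LEVELS))

    def subset(self, indices) -> "SampleSet":
        idx = np.asarray(indices)
        return SampleSet(self.samples[idx], self.labels[idx], self.subject_ids[idx])

    @staticmethod
    def concatenate(sets: Sequence["SampleSet"]) -> "SampleSet":
        return SampleSet(
            np.concatenate([s.samples for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
        )

    def save(self, path) -> None:
        """Persist as ``<path>.npz`` plus a JSON sidecar ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), samples=self.samples)
        sidecar = {
            "labels": self.labels.tolist(),
            "subject_ids": [str(s) for s in self.subject_ids],
            "n_in": self.n_in,
            "n_samples": len(self),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(path) -> "SampleSet":
        path = Path(path)
        samples = np.load(path.with_suffix(".npz"))["samples"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return SampleSet(samples, meta["labels"], meta["subject_ids"])


@dataclass(frozen=True)
class TaskSpec:
    """One evaluation task: three subjects (one per level) and sample counts."""

    name: str
    subjects: tuple[str, ...]
    n_train: int = 1200
    n_test: int = 600

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise CopDataError("sample counts must be positive")
        if len(self.subjects) != len(LEVELS):
            raise CopDataError("a task needs exactly one subject per level")


#: The four subject pairings evaluated in the study design this package
#: follows: two subjects per level, crossed so each task sees one H, one M
#: and one N subject.
STANDARD_TASKS: Mapping[str, TaskSpec] = {
    "T1": TaskSpec("T1", ("H#1", "M#1", "N#1")),
    "T2": TaskSpec("T2", ("H#2", "M#2", "N#2")),
    "T3": TaskSpec("T3", ("H#1", "M#2", "N#1")),
    "T4": TaskSpec("T4", ("H#2", "M#1", "N#2")),
}


def _sniff_table(path: Path) -> tuple[pd.DataFrame, bool]:
    text_lines = path.read_text().strip().splitlines()
    if not text_lines:
        raise CopDataError(f"{path}: empty recording file")
    first = text_lines[0]
    delim = "\t" if "\t" in first else ","
    tokens = [t.strip() for t in first.split(delim)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens)
    try:
        frame = pd.read_csv(path, sep=delim, header=0 if has_header else None)
    except pd.errors.ParserError as exc:
        raise CopDataError(f"{path}: {exc}") from exc
    return frame, has_header


def read_recording(path, subject_id: str, level: str, fs: float = 100.0) -> CopRecording:
    """Read a delimited-text recording with columns ``t, x, y`` or ``x, y``.

    The sampling rate comes from the manifest/config, not from the time
    column. Malformed or non-finite cells raise :class:`ParseError` naming
    the first offending line (1-based, counting the header).
    """
    path = Path(path)
    frame, had_header = _sniff_table(path)
    if frame.shape[1] == 3:
        frame = frame.iloc[:, 1:]
    elif frame.shape[1] != 2:
        raise CopDataError(
            f"{path}: expected 2 or 3 columns, found {frame.shape[1]}"
        )
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ParseError(
            f"{path}: malformed or non-finite value at line {row + 1 + int(had_header)}"
        )
    return CopRecording(subject_id, level, values[:, 0], values[:, 1], fs=fs)


def write_recording(rec: CopRecording, path) -> None:
    """Write a recording as CSV with header ``t,x,y`` (t in seconds)."""
    t = np.arange(rec.n_steps) / rec.fs
    frame = pd.DataFrame({"t": t, "x": rec.x, "y": rec.y})
    frame.to_csv(path, index=False, float_format="%.10g")


def read_manifest(path) -> list[CopRecording]:
    """Load all recordings listed in a manifest CSV.

    The manifest has columns ``subject_id, level, path, fs``; relative
    recording paths resolve against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = {"subject_id", "level", "path", "fs"}
    if not required.issubset(table.columns):
        raise CopDataError(
            f"{path}: manifest must have columns {sorted(required)}"
        )
    recordings = []
    for row in table.itertuples(index=False):
        rec_path = Path(row.path)
        if not rec_path.is_absolute():
            rec_path = path.parent / rec_path
        recordings.append(
            read_recording(rec_path, str(row.subject_id), str(row.level), fs=float(row.fs))
        )
    return recordings


def write_manifest(recordings: Iterable[CopRecording], directory) -> Path:
    """Write each recording as ``<subject_id>.csv`` plus a ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = rec.subject_id.replace("#", "") + ".csv"
        write_recording(rec, directory / fname)
        rows.append(
            {"subject_id": rec.subject_id, "level": rec.level, "path": fname, "fs": rec.fs}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def window_recording(rec: CopRecording, n_in: int, stride: int) -> SampleSet:
    """Slice a recording into ``[2, n_in]`` windows at the given stride.

    Window ``i`` covers time steps ``[i*stride, i*stride + n_in)``; there are
    ``floor((T - n_in)/stride) + 1`` of them. All windows inherit the
    recording's level label.
    """
    if stride < 1:
        raise CopDataError("stride must be >= 1")
    if n_in < 1:
        raise CopDataError("window length must be >= 1")
    T = rec.n_steps
    if n_in > T:
        raise InsufficientDataError(
            f"{rec.subject_id}: window length {n_in} exceeds recording length {T}"
        )
    n_windows = (T - n_in) // stride + 1
    chans = rec.channels()
    starts = np.arange(n_windows) * stride
    samples = np.stack([chans[:, s : s + n_in] for s in starts])
    return SampleSet(
        samples,
        np.full(n_windows, rec.label),
        np.full(n_windows, rec.subject_id, dtype=object),
    )


def build_task(
    task: TaskSpec,
    recordings: Sequence[CopRecording],
    n_in: int = 200,
    seed: int = 0,
    stride: int | None = None,
) -> tuple[SampleSet, SampleSet]:
    """Assemble a balanced, leakage-free train/test pair for a task.

    Per subject, windows are split chronologically: the earliest
    ``n_train/3`` become training samples and the latest ``n_test/3``
    testing samples, with enough unused windows in between that no time
    step is shared between a training and a testing window. The pooled
    sets are then shuffled with the given seed.
    """
    if stride is None:
        stride = max(n_in // 2, 1)
    if task.n_train % len(LEVELS) or task.n_test % len(LEVELS):
        raise CopDataError("n_train and n_test must be divisible by 3")
    per_train = task.n_train // len(LEVELS)
    per_test = task.n_test // len(LEVELS)

    by_id = {rec.subject_id: rec for rec in recordings}
    missing = [s for s in task.subjects if s not in by_id]
    if missing:
        raise CopDataError(f"task {task.name}: missing recordings for {missing}")

    train_parts, test_parts = [], []
    for sid in task.subjects:
        windows = window_recording(by_id[sid], n_in, stride)
        n_avail = len(windows)
        needed = per_train + per_test
        if n_avail < needed:
            raise InsufficientDataError(
                f"{sid}: need {needed} windows, only {n_avail} available "
                f"(T={by_id[sid].n_steps}, n_in={n_in}, stride={stride})"
            )
        train_idx = np.arange(per_train)
        test_idx = np.arange(n_avail - per_test, n_avail)
        # last training step vs first testing step: reject any overlap
        train_end = (per_train - 1) * stride + n_in
        test_start = (n_avail - per_test) * stride
        if test_start < train_end:
            raise InsufficientDataError(
                f"{sid}: chronological split would share time steps "
                f"(train ends at step {train_end}, test starts at {test_start}); "
                f"need {needed + (n_in - stride + stride - 1) // stride} windows, "
                f"have {n_avail}"
            )
        train_parts.append(windows.subset(train_idx))
        test_parts.append(windows.subset(test_idx))

    rng = np.random.default_rng(seed)
    train = SampleSet.concatenate(train_parts)
    test = SampleSet.concatenate(test_parts)
    train = train.subset(rng.permutation(len(train)))
    test = test.subset(rng.permutation(len(test)))
    return train, test


def standardize(
    train: SampleSet, test: SampleSet
) -> tuple[SampleSet, SampleSet, dict]:
    """Z-score both sets per channel using statistics of the training set.

    A zero standard deviation is replaced by 1 so constant channels pass
    through unchanged.
    """
    if len(train) == 0:
        raise CopDataError("cannot standardize with an empty training set")
    mean = train.samples.mean(axis=(0, 2), keepdims=True)
    std = train.samples.std(axis=(0, 2), keepdims=True)
    std = np.where(std == 0, 1.0, std)

    def _apply(s: SampleSet) -> SampleSet:
        return SampleSet((s.samples - mean) / std, s.labels, s.subject_ids)

    stats = {"mean": mean.ravel().tolist(), "std": std.ravel().tolist()}
    return _apply(train), _apply(test), stats
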