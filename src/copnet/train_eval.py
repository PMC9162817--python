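"""Training loop, task runner, ablation sweeps and feature visualization.

Experiments follow the study protocol: each (task, method) pair is trained
``repeats`` times (fresh initialization and fresh mini-batch shuffling per
repeat, fixed test set) and the mean test accuracy over repeats is
reported. Two ablation sweeps vary the number of convolutional filters and
the number of training samples; learned hidden-layer features are
projected to 2D with t-SNE for visual inspection of class separation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix, silhouette_score

from .cop_data import (
    LEVELS,
    CopRecording,
    InsufficientDataError,
    SampleSet,
    TaskSpec,
    build_task,
    standardize,
)
from .msrc_model import BuiltModel, SwayNetClassifier

__all__ = [
    "TrainConfig",
    "RunResult",
    "derive_seed",
    "train",
    "evaluate",
    "run_task",
    "ablate_filters",
    "ablate_samples",
    "visualize_features",
]

DEFAULT_FILTER_SWEEP = (1, 5, 10, 15, 20)
DEFAULT_SAMPLE_SWEEP = (300, 600, 900, 1200)


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch Adam training configuration.

    Defaults are the study settings: batch size 8, 100 epochs, learning
    rate 1e-4, three repeats per experiment. ``validation_fraction`` is
    the share of training samples a caller may hold out for monitoring;
    the task runner itself trains on the full training set and evaluates
    on the final epoch.
    """

    batch_size: int = 8
    epochs: int = 100
    learning_rate: float = 1e-4
    repeats: int = 3
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.repeats < 1:
            raise ValueError("batch_size, epochs and repeats must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class RunResult:
    """Outcome of one (task, method) experiment."""

    task: str
    method: str
    per_repeat_test_accuracy: list[float]
    mean_test_accuracy: float
    loss_history: list[list[float]]
    confusion: np.ndarray
    features: np.ndarray | None = None
    feature_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "method": self.method,
            "per_repeat_test_accuracy": self.per_repeat_test_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "loss_history": self.loss_history,
            "confusion": np.asarray(self.confusion).tolist(),
        }

    def save(self, path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        if self.features is not None:
            np.savez(
                path.with_suffix(".features.npz"),
                features=self.features,
                labels=self.feature_labels,
            )

    @staticmethod
    def load(path) -> "RunResult":
        path = Path(path)
        d = json.loads(path.read_text())
        result = RunResult(
            task=d["task"],
            method=d["method"],
            per_repeat_test_accuracy=d["per_repeat_test_accuracy"],
            mean_test_accuracy=d["mean_test_accuracy"],
            loss_history=d["loss_history"],
            confusion=np.asarray(d["confusion"]),
        )
        feat_path = path.with_suffix(".features.npz")
        if feat_path.exists():
            data = np.load(feat_path)
            result.features = data["features"]
            result.feature_labels = data["labels"]
        return result


def derive_seed(*parts) -> int:
    """Deterministically fold seed components into one 31-bit seed.

    Strings are hashed stably; the same tuple always yields the same
    seed, and distinct tuples yield independent streams.
    """
    entropy = [
        int.from_bytes(str(p).encode(), "little") if isinstance(p, str) else int(p)
        for p in parts
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def train(
    model: BuiltModel,
    train_set: SampleSet,
    cfg: TrainConfig,
    repeat_seed: int = 0,
) -> tuple[BuiltModel, list[float]]:
    """Train a built model in place; return it with its per-epoch loss."""
    history = model.fit_minibatch(
        train_set.samples,
        train_set.labels,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        seed=derive_seed(cfg.seed, repeat_seed, "train"),
    )
    return model, history


def evaluate(model, test: SampleSet) -> tuple[float, np.ndarray]:
    """Accuracy and 3x3 confusion matrix on a test set.

    Accepts a :class:`BuiltModel` or a fitted :class:`SwayNetClassifier`.
    Predictions take the argmax of the class probabilities; ties go to
    the lowest class index.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    if isinstance(model, BuiltModel):
        probs = model.forward(test.samples)
        pred = np.argmax(probs, axis=1)
    else:
        pred = model.predict(test.samples)
    labels = list(range(len(LEVELS)))
    conf = confusion_matrix(test.labels, pred, labels=labels)
    accuracy = float(np.trace(conf) / conf.sum())
    return accuracy, conf


def _make_classifier(method: str, cfg: TrainConfig, seed: int, **overrides) -> SwayNetClassifier:
    return SwayNetClassifier(
        kind=method.lower(),
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        random_state=seed,
        **overrides,
    )


def _run_on_sets(
    task_name: str,
    method: str,
    train_set: SampleSet,
    test_set: SampleSet,
    cfg: TrainConfig,
    store_features: bool = False,
    **model_overrides,
) -> RunResult:
    model_overrides.setdefault("n_in", train_set.n_in)
    accs, histories = [], []
    confusion = np.zeros((len(LEVELS), len(LEVELS)), dtype=int)
    features = feature_labels = None
    for r in range(cfg.repeats):
        seed = derive_seed(cfg.seed, task_name, method, r)
        clf = _make_classifier(method, cfg, seed, **model_overrides)
        clf.fit(train_set.samples, train_set.labels)
        acc, conf = evaluate(clf, test_set)
        accs.append(acc)
        histories.append(clf.loss_history_)
        confusion += conf
        if store_features and r == cfg.repeats - 1:
            features = clf.transform(test_set.samples)
            feature_labels = test_set.labels.copy()
    return RunResult(
        task=task_name,
        method=method.upper(),
        per_repeat_test_accuracy=accs,
        mean_test_accuracy=float(np.mean(accs)),
        loss_history=histories,
        confusion=confusion,
        features=features,
        feature_labels=feature_labels,
    )


def run_task(
    task: TaskSpec,
    method: str,
    cfg: TrainConfig,
    recordings: Sequence[CopRecording],
    n_in: int = 200,
    stride: int | None = None,
    apply_standardize: bool = True,
    store_features: bool = False,
    **model_overrides,
) -> RunResult:
    """Run one (task, method) experiment with repeat-averaging.

    Builds the balanced, chronologically split train/test pair for the
    task, optionally z-scores it with training statistics, trains
    ``cfg.repeats`` independent models and averages their test accuracy.
    """
    split_seed = derive_seed(cfg.seed, task.name, "split")
    train_set, test_set = build_task(task, recordings, n_in=n_in, seed=split_seed, stride=stride)
    if apply_standardize:
        train_set, test_set, _ = standardize(train_set, test_set)
    return _run_on_sets(
        task.name, method, train_set, test_set, cfg,
        store_features=store_features, **model_overrides,
    )


def ablate_filters(
    task: TaskSpec,
    filter_counts: Sequence[int],
    cfg: TrainConfig,
    recordings: Sequence[CopRecording],
    n_in: int = 200,
    stride: int | None = None,
    method: str = "msrc",
) -> pd.DataFrame:
    """Sweep the per-layer convolutional filter count.

    All counts see the identical train/test split and repeat seeds, so
    rows differ only in model capacity.
    """
    if any(c < 1 for c in filter_counts):
        raise ValueError("filter counts must be >= 1")
    split_seed = derive_seed(cfg.seed, task.name, "split")
    train_set, test_set = build_task(task, recordings, n_in=n_in, seed=split_seed, stride=stride)
    train_set, test_set, _ = standardize(train_set, test_set)
    rows = []
    for count in filter_counts:
        result = _run_on_sets(
            task.name, method, train_set, test_set, cfg, filters_per_conv=int(count)
        )
        rows.append(
            {
                "filters_per_conv": int(count),
                "mean_test_accuracy": result.mean_test_accuracy,
                **{
                    f"repeat{r}_accuracy": a
                    for r, a in enumerate(result.per_repeat_test_accuracy)
                },
            }
        )
    return pd.DataFrame(rows)


def balanced_nested_subsample(
    labels: np.ndarray, sizes: Sequence[int], seed: int
) -> dict[int, np.ndarray]:
    """Nested, class-balanced index subsets: smaller sets are prefixes.

    Each class's indices are permuted once; a subset of total size ``s``
    takes the first ``s / n_classes`` indices of every class, so subsets
    are nested across sizes and exactly balanced.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    per_class_order = {
        c: rng.permutation(np.flatnonzero(labels == c)) for c in classes
    }
    out = {}
    for s in sizes:
        if s % len(classes):
            raise ValueError(f"subset size {s} not divisible by {len(classes)} classes")
        per = s // len(classes)
        if any(len(per_class_order[c]) < per for c in classes):
            raise InsufficientDataError(
                f"subset size {s} exceeds available balanced pool"
            )
        out[int(s)] = np.concatenate([per_class_order[c][:per] for c in classes])
    return out


def ablate_samples(
    task: TaskSpec,
    train_sizes: Sequence[int],
    cfg: TrainConfig,
    recordings: Sequence[CopRecording],
    n_in: int = 200,
    stride: int | None = None,
    method: str = "msrc",
) -> pd.DataFrame:
    """Sweep the number of training samples on a nested subsample chain."""
    split_seed = derive_seed(cfg.seed, task.name, "split")
    train_set, test_set = build_task(task, recordings, n_in=n_in, seed=split_seed, stride=stride)
    train_set, test_set, _ = standardize(train_set, test_set)
    subsets = balanced_nested_subsample(
        train_set.labels, train_sizes, derive_seed(cfg.seed, task.name, "subsample")
    )
    rows = []
    for size in train_sizes:
        sub = train_set.subset(subsets[int(size)])
        result = _run_on_sets(task.name, method, sub, test_set, cfg)
        rows.append(
            {
                "n_train": int(size),
                "mean_test_accuracy": result.mean_test_accuracy,
                **{
                    f"repeat{r}_accuracy": a
                    for r, a in enumerate(result.per_repeat_test_accuracy)
                },
            }
        )
    return pd.DataFrame(rows)


def visualize_features(
    result: RunResult,
    perplexity: float = 30.0,
    seed: int = 0,
    out_path=None,
) -> tuple[np.ndarray, float] | None:
    """t-SNE projection of stored hidden-layer features to 2D.

    Returns the [n, 2] embedding and its silhouette score (higher means
    better class separation in the projected space); optionally writes a
    scatter plot colored by true class. Returns ``None`` with a warning
    when the features are degenerate (all identical).
    """
    if result.features is None:
        raise ValueError(
            "RunResult has no stored features; rerun with store_features=True"
        )
    feats = np.asarray(result.features, dtype=float)
    labels = np.asarray(result.feature_labels, dtype=int)
    if len(feats) < 10:
        raise ValueError("need at least 10 samples for a meaningful embedding")
    if np.allclose(feats, feats[0]):
        warnings.warn("features are degenerate (all identical); skipping embedding")
        return None
    emb = TSNE(
        n_components=2,
        perplexity=min(perplexity, (len(feats) - 1) / 3),
        init="pca",
        random_state=seed,
    ).fit_transform(feats)
    score = float(silhouette_score(emb, labels))
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, level in enumerate(LEVELS):
            mask = labels == lab
            ax.scatter(emb[mask, 0], emb[mask, 1], s=8, label=level, alpha=0.7)
        ax.set_title(
            f"{result.task} {result.method} features (silhouette {score:.2f})"
        )
        ax.legend(title="level")
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return emb, score
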