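"""Model architectures for balance-control classification.

The centrepiece is the multi-scale residual connected network (MSRC): three
parallel convolutional branches with kernel sizes 3, 10 and 20 capture
local through global temporal sway patterns. Each branch stacks two
residual blocks (two same-padded convolutions plus a short-cut add, Leaky
ReLU after the sum) with max pooling after each block; branch outputs are
flattened, concatenated, and classified through a 128-unit fully-connected
layer, dropout, and a softmax head.

Four comparison architectures share the training setup:

* ``nn``    — multilayer perceptron, one hidden layer of 1000 units;
* ``dnn``   — deeper perceptron, hidden layers 1000 / 1000 / 500;
* ``dscnn`` — single-scale variant of MSRC (one branch, kernel 10);
* ``wores`` — MSRC with the residual short-cuts removed.

:class:`SwayNetClassifier` wraps all of them behind the scikit-learn
estimator interface; the module-level functions (:func:`build_model`,
:func:`forward`, :func:`extract_features`, :func:`count_parameters`) are
thin functional views of the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import backend as B

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "BuiltModel",
    "DivergenceError",
    "build_model",
    "forward",
    "extract_features",
    "count_parameters",
    "save_model",
    "load_model",
    "SwayNetClassifier",
]

MODEL_KINDS = ("msrc", "nn", "dnn", "dscnn", "wores")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture."""

    kind: str = "msrc"
    n_in: int = 200
    n_channels: int = 2
    n_classes: int = 3
    branch_kernel_sizes: tuple[int, ...] = (3, 10, 20)
    blocks_per_branch: int = 2
    convs_per_block: int = 2
    filters_per_conv: int = 10
    pool_size: int = 2
    fc_hidden: int = 128
    leaky_slope: float = 0.01
    dropout_rate: float = 0.2
    residual: bool = True
    single_scale_kernel: int = 10
    mlp_hidden: tuple[int, ...] = (1000,)  # nn/dnn only

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        for name in (
            "n_in", "n_channels", "n_classes", "blocks_per_branch",
            "convs_per_block", "filters_per_conv", "pool_size", "fc_hidden",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        object.__setattr__(
            self, "branch_kernel_sizes", tuple(self.branch_kernel_sizes)
        )
        object.__setattr__(self, "mlp_hidden", tuple(self.mlp_hidden))

    @staticmethod
    def for_kind(kind: str, **overrides) -> "ModelSpec":
        """Canonical spec for each architecture family."""
        kind = kind.lower()
        if kind == "nn":
            overrides.setdefault("mlp_hidden", (1000,))
        elif kind == "dnn":
            overrides.setdefault("mlp_hidden", (1000, 1000, 500))
        elif kind == "wores":
            overrides["residual"] = False
        return ModelSpec(kind=kind, **overrides)

    def effective_kernels(self) -> tuple[int, ...]:
        """Branch kernel sizes actually built (dscnn collapses to one)."""
        if self.kind == "dscnn":
            return (self.single_scale_kernel,)
        return self.branch_kernel_sizes

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("branch_kernel_sizes", "mlp_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelSpec(**d)


def _conv_block(
    spec: ModelSpec, c_in: int, kernel: int, rng: np.random.Generator
) -> B.Layer:
    """One (residual) block: convs with activations, optional short-cut."""
    F = spec.filters_per_conv
    main: list[B.Layer] = []
    for i in range(spec.convs_per_block):
        last = i == spec.convs_per_block - 1
        main.append(
            B.Conv1dSame(
                c_in if i == 0 else F, F, kernel, rng,
                # in a residual block the last conv's activation comes
                # after the short-cut sum; without residual it is fused
                activation_slope=None if (last and spec.residual) else spec.leaky_slope,
            )
        )
    if spec.residual:
        shortcut = None if c_in == F else B.Conv1dSame(c_in, F, 1, rng)
        return B.ResidualBlock(B.Sequential(main), shortcut, spec.leaky_slope)
    return B.Sequential(main)


def _build_branch(
    spec: ModelSpec, kernel: int, rng: np.random.Generator
) -> tuple[B.Sequential, int]:
    layers: list[B.Layer] = []
    c_in = spec.n_channels
    length = spec.n_in
    for _ in range(spec.blocks_per_branch):
        layers.append(_conv_block(spec, c_in, kernel, rng))
        layers.append(B.MaxPool1d(spec.pool_size))
        c_in = spec.filters_per_conv
        length //= spec.pool_size
        if length == 0:
            raise ValueError(
                f"branch with kernel {kernel}: pooled length reached 0 "
                f"(n_in={spec.n_in}, pool={spec.pool_size}, "
                f"blocks={spec.blocks_per_branch})"
            )
    layers.append(B.Flatten())
    return B.Sequential(layers), c_in * length


@dataclass
class BuiltModel:
    """A constructed network: spec, layers, and the softmax head.

    ``feature_end`` indexes the layer boundary whose activations are the
    model's high-level representation (post-activation of the last hidden
    fully-connected layer).
    """

    spec: ModelSpec
    net: B.Sequential
    feature_end: int
    head = None  # set in __post_init__

    def __post_init__(self) -> None:
        self.head = B.SoftmaxCrossEntropy()

    def params(self) -> list[B.Param]:
        return self.net.params()

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=B.DTYPE)
        expect = (self.spec.n_channels, self.spec.n_in)
        if batch.ndim != 3 or batch.shape[1:] != expect:
            raise ValueError(
                f"expected batch of shape [n, {expect[0]}, {expect[1]}], "
                f"got {batch.shape}"
            )
        return batch

    @staticmethod
    def _to_internal(batch: np.ndarray) -> np.ndarray:
        # backend layers run length-major: [n, 2, n_in] -> [n, n_in, 2]
        return np.ascontiguousarray(batch.transpose(0, 2, 1))

    def logits(self, batch: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.net.forward(self._to_internal(self._check_batch(batch)), rng)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities in eval mode (dropout off); rows sum to 1."""
        return self.head.probs(self.logits(batch))

    def extract_features(self, batch: np.ndarray) -> np.ndarray:
        """Hidden-layer activations (eval mode), shape [n, fc_hidden]."""
        return self.net.forward_upto(
            self._to_internal(self._check_batch(batch)), self.feature_end
        )

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def fit_minibatch(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        seed: int,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> list[float]:
        """Mini-batch Adam training on mean cross-entropy.

        Each epoch reshuffles the samples; the last short batch is kept.
        Returns the per-epoch mean training loss. Fully reproducible from
        ``seed`` (one generator drives both shuffling and dropout).
        """
        X = self._to_internal(self._check_batch(X))
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("cannot train on an empty sample set")
        rng = np.random.default_rng(seed)
        opt = B.Adam(self.params(), lr=learning_rate, beta1=beta1, beta2=beta2, eps=eps)
        history: list[float] = []
        n = len(X)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.net.forward(X[idx], rng)
                loss, dlogits = self.head.loss(logits, y[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                self.net.backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history


def save_model(model: BuiltModel, path) -> None:
    """Checkpoint a model as ``.npz``: flat parameter arrays plus the
    JSON-serialized spec, so a load reconstructs the exact network."""
    import json

    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, spec=json.dumps(model.spec.to_dict()), **arrays)


def load_model(path) -> BuiltModel:
    """Rebuild a checkpointed model (topology from the embedded spec)."""
    import json

    data = np.load(path, allow_pickle=False)
    spec = ModelSpec.from_dict(json.loads(str(data["spec"])))
    model = build_model(spec, seed=0)
    params = model.params()
    for i, p in enumerate(params):
        p.value[...] = data[f"p{i}"]
    return model


def build_model(spec: ModelSpec, seed: int = 0) -> BuiltModel:
    """Construct a network of the given kind with seeded weight init."""
    rng = np.random.default_rng(seed)
    layers: list[B.Layer] = []

    if spec.kind in ("nn", "dnn"):
        layers.append(B.Flatten())
        width = spec.n_channels * spec.n_in
        for h in spec.mlp_hidden:
            layers.append(B.Dense(width, h, rng, activation_slope=spec.leaky_slope))
            layers.append(B.Dropout(spec.dropout_rate))
            width = h
        layers.append(B.Dense(width, spec.n_classes, rng))
    else:
        kernels = spec.effective_kernels()
        branches, widths = [], []
        for k in kernels:
            branch, w = _build_branch(spec, k, rng)
            branches.append(branch)
            widths.append(w)
        if len(branches) == 1:
            layers.extend(branches[0].layers)
        else:
            layers.append(B.ParallelConcat(branches))
        layers.append(
            B.Dense(sum(widths), spec.fc_hidden, rng, activation_slope=spec.leaky_slope)
        )
        layers.append(B.Dropout(spec.dropout_rate))
        layers.append(B.Dense(spec.fc_hidden, spec.n_classes, rng))

    # features = activations just before the final classifying layer
    # (dropout is the identity in eval mode, so the boundary sits after it)
    feature_end = len(layers) - 1
    return BuiltModel(spec=spec, net=B.Sequential(layers), feature_end=feature_end)


def forward(model: BuiltModel, batch: np.ndarray) -> np.ndarray:
    return model.forward(batch)


def extract_features(model: BuiltModel, batch: np.ndarray) -> np.ndarray:
    return model.extract_features(batch)


def count_parameters(model: BuiltModel) -> int:
    return model.count_parameters()


class SwayNetClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Scikit-learn estimator over the balance-control architectures.

    Parameters mirror :class:`ModelSpec` plus the training configuration
    (mini-batch Adam on cross-entropy). ``X`` is a float array of shape
    ``[n, 2, n_in]`` (two-channel windows) or ``[n, 2 * n_in]`` (flattened,
    channel-major). ``transform`` returns the hidden-layer features used
    for visualization.

    Examples
    --------
    >>> clf = SwayNetClassifier(kind="msrc", epochs=5, random_state=0)
    >>> clf.fit(X_train, y_train).score(X_test, y_test)  # doctest: +SKIP
    """

    def __init__(
        self,
        kind: str = "msrc",
        n_in: int = 200,
        branch_kernel_sizes: tuple[int, ...] = (3, 10, 20),
        blocks_per_branch: int = 2,
        convs_per_block: int = 2,
        filters_per_conv: int = 10,
        pool_size: int = 2,
        fc_hidden: int = 128,
        leaky_slope: float = 0.01,
        dropout_rate: float = 0.2,
        single_scale_kernel: int = 10,
        epochs: int = 100,
        batch_size: int = 8,
        learning_rate: float = 1e-4,
        random_state: int | None = None,
    ):
        self.kind = kind
        self.n_in = n_in
        self.branch_kernel_sizes = branch_kernel_sizes
        self.blocks_per_branch = blocks_per_branch
        self.convs_per_block = convs_per_block
        self.filters_per_conv = filters_per_conv
        self.pool_size = pool_size
        self.fc_hidden = fc_hidden
        self.leaky_slope = leaky_slope
        self.dropout_rate = dropout_rate
        self.single_scale_kernel = single_scale_kernel
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _spec(self, n_classes: int) -> ModelSpec:
        return ModelSpec.for_kind(
            self.kind,
            n_in=self.n_in,
            n_classes=n_classes,
            branch_kernel_sizes=tuple(self.branch_kernel_sizes),
            blocks_per_branch=self.blocks_per_branch,
            convs_per_block=self.convs_per_block,
            filters_per_conv=self.filters_per_conv,
            pool_size=self.pool_size,
            fc_hidden=self.fc_hidden,
            leaky_slope=self.leaky_slope,
            dropout_rate=self.dropout_rate,
            single_scale_kernel=self.single_scale_kernel,
        )

    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 2 * self.n_in:
                raise ValueError(
                    f"flattened X must have {2 * self.n_in} columns, got {X.shape[1]}"
                )
            X = X.reshape(len(X), 2, self.n_in)
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.n_in:
            raise ValueError(f"X must have shape [n, 2, {self.n_in}], got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "this SwayNetClassifier instance is not fitted yet"
            )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y) -> "SwayNetClassifier":
        X = self._coerce_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        seed = 0 if self.random_state is None else int(self.random_state)
        self.model_ = build_model(self._spec(len(self.classes_)), seed=seed)
        self.loss_history_ = self.model_.fit_minibatch(
            X,
            y_idx,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=seed + 1,
        )
        self.n_features_in_ = 2 * self.n_in
        self.n_parameters_ = self.model_.count_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.forward(self._coerce_X(X))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        # np.argmax takes the lowest index on ties, the documented rule
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def transform(self, X) -> np.ndarray:
        """Hidden-layer feature matrix, shape [n, fc_hidden] for conv nets."""
        self._check_fitted()
        return self.model_.extract_features(self._coerce_X(X))
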