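"""Multilayer-perceptron engine shared by probe ranking and network inference.

The model is deliberately minimal: one hidden layer (two logistic-sigmoid
units by default) and a logistic-sigmoid output, trained by online
back-propagation with momentum under Monte-Carlo cross-validation (MCCV).
Each MCCV split partitions the samples into train / test / validation
subsets (60/20/20 by default): the train subset drives the weight updates,
the test subset drives early stopping (the weights returned are the snapshot
at the best test mean-squared error), and the validation subset is never
touched during training — its MSE is reported as a held-out performance
figure.

The per-sample loss is the squared error (o - y)^2; its gradient therefore
carries a factor 2 relative to the 1/2-loss convention (equivalent up to a
rescaled learning rate). The momentum update is the classical heavy-ball
rule v <- momentum * v - lr * grad; w <- w + v, which reduces to plain
stochastic gradient descent at momentum 0.

The inner training loop is JIT-compiled with numba; all randomness (weight
initialisation, per-epoch sample shuffling, MCCV partitions) derives from
explicit integer seeds so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from luminet.dataset import ExpressionDataset
from luminet.exceptions import (
    ConfigError,
    DataError,
    NumericalError,
    ShapeError,
    SplitError,
)

__all__ = [
    "TrainingConfig",
    "DataSplit",
    "TrainedMLP",
    "scale_to_unit",
    "make_mccv_splits",
    "train_mlp",
    "predict",
    "evaluate_mse",
    "sample_gradients",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the perceptron trainer.

    Defaults follow the classical small-net recipe for this workflow:
    two hidden sigmoid units, learning rate 0.1, momentum 0.5, at most
    3000 epochs with early stopping after 1000 epochs without a new best
    test MSE.
    """

    n_hidden: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    max_epochs: int = 3000
    patience_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum must be in [0, 1)")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if self.patience_epochs < 0:
            raise ConfigError("patience_epochs must be >= 0")
        if self.patience_epochs > self.max_epochs:
            raise ConfigError("patience_epochs must be <= max_epochs")


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train / test / validation sample indices of one MCCV draw."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    validation_idx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("train_idx", "test_idx", "validation_idx"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64)
            )
        all_idx = np.concatenate(
            [self.train_idx, self.test_idx, self.validation_idx]
        )
        if len(np.unique(all_idx)) != len(all_idx):
            raise SplitError("train/test/validation subsets overlap")


@dataclass
class TrainedMLP:
    """Weights of a trained 1-hidden-layer sigmoid perceptron.

    The stored weights are the snapshot taken at the epoch with the lowest
    test-subset MSE, not the final-epoch weights.
    """

    w_in_hidden: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    w_hidden_out: np.ndarray  # (n_hidden,)
    b_out: float
    best_test_mse: float
    epochs_run: int
    snapshot_epoch: int
    validation_mse: float | None = None
    seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self.w_in_hidden.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in_hidden.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "w_in_hidden": self.w_in_hidden.tolist(),
                "b_hidden": self.b_hidden.tolist(),
                "w_hidden_out": self.w_hidden_out.tolist(),
                "b_out": self.b_out,
                "best_test_mse": self.best_test_mse,
                "epochs_run": self.epochs_run,
                "snapshot_epoch": self.snapshot_epoch,
                "validation_mse": self.validation_mse,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "TrainedMLP":
        d = json.loads(payload)
        return cls(
            w_in_hidden=np.asarray(d["w_in_hidden"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            w_hidden_out=np.asarray(d["w_hidden_out"], dtype=float),
            b_out=float(d["b_out"]),
            best_test_mse=float(d["best_test_mse"]),
            epochs_run=int(d["epochs_run"]),
            snapshot_epoch=int(d["snapshot_epoch"]),
            validation_mse=(
                None if d.get("validation_mse") is None else float(d["validation_mse"])
            ),
            seed=int(d.get("seed", 0)),
        )


def scale_to_unit(dataset: ExpressionDataset) -> ExpressionDataset:
    """Linearly map every probe to the unit interval.

    Each probe's minimum goes to 0 and maximum to 1; a constant probe maps
    to 0.5 everywhere. Required because both network layers are logistic
    sigmoids, whose useful dynamic range is (0, 1).
    """
    values = dataset.values
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        culprit = dataset.probe_ids[int(np.flatnonzero(bad)[0])]
        raise DataError(f"probe {culprit!r} contains non-finite values")
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - lo) / span
    scaled[constant] = 0.5
    return ExpressionDataset(
        values=scaled,
        probe_ids=list(dataset.probe_ids),
        sample_ids=list(dataset.sample_ids),
        labels=None if dataset.labels is None else dataset.labels.copy(),
    )


def make_mccv_splits(
    n_samples: int,
    n_iterations: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[DataSplit]:
    """Draw independent random train/test/validation partitions.

    Test and validation sizes are floor(fraction * n); the remainder goes
    to train (e.g. n=278 gives 168/55/55).
    """
    if n_samples < 5:
        raise SplitError(f"need at least 5 samples for MCCV, got {n_samples}")
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must sum to 1")
    n_test = int(np.floor(fractions[1] * n_samples))
    n_val = int(np.floor(fractions[2] * n_samples))
    n_train = n_samples - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise SplitError("every subset must receive at least one sample")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_iterations):
        perm = rng.permutation(n_samples)
        splits.append(
            DataSplit(
                train_idx=np.sort(perm[:n_train]),
                test_idx=np.sort(perm[n_train : n_train + n_test]),
                validation_idx=np.sort(perm[n_train + n_test :]),
            )
        )
    return splits


@njit(cache=True)
def _forward_mse(X, y, W1, b1, w2, b2):  # pragma: no cover - jitted
    n = X.shape[0]
    total = 0.0
    for s in range(n):
        z = b2
        for h in range(W1.shape[1]):
            a = b1[h]
            for i in range(W1.shape[0]):
                a += W1[i, h] * X[s, i]
            z += w2[h] * (1.0 / (1.0 + np.exp(-a)))
        o = 1.0 / (1.0 + np.exp(-z))
        d = o - y[s]
        total += d * d
    return total / n


@njit(cache=True)
def _train_kernel(
    Xtr, ytr, Xte, yte, W1, b1, w2, b2, lr, mom, max_epochs, patience, perms
):  # pragma: no cover - jitted
    n_in, n_hid = W1.shape
    vW1 = np.zeros((n_in, n_hid))
    vb1 = np.zeros(n_hid)
    vw2 = np.zeros(n_hid)
    vb2 = 0.0
    hidden = np.empty(n_hid)

    best_mse = np.inf
    best_epoch = 0
    bW1 = W1.copy()
    bb1 = b1.copy()
    bw2 = w2.copy()
    bb2 = b2
    since_best = 0
    epochs_run = 0
    nan_epoch = -1

    for epoch in range(max_epochs):
        for k in range(Xtr.shape[0]):
            s = perms[epoch, k]
            # forward
            z = b2
            for h in range(n_hid):
                a = b1[h]
                for i in range(n_in):
                    a += W1[i, h] * Xtr[s, i]
                hidden[h] = 1.0 / (1.0 + np.exp(-a))
                z += w2[h] * hidden[h]
            o = 1.0 / (1.0 + np.exp(-z))
            # backward: loss (o - y)^2
            delta_o = 2.0 * (o - ytr[s]) * o * (1.0 - o)
            vb2 = mom * vb2 - lr * delta_o
            b2 += vb2
            for h in range(n_hid):
                delta_h = delta_o * w2[h] * hidden[h] * (1.0 - hidden[h])
                vw2[h] = mom * vw2[h] - lr * delta_o * hidden[h]
                w2[h] += vw2[h]
                vb1[h] = mom * vb1[h] - lr * delta_h
                b1[h] += vb1[h]
                for i in range(n_in):
                    vW1[i, h] = mom * vW1[i, h] - lr * delta_h * Xtr[s, i]
                    W1[i, h] += vW1[i, h]
        epochs_run = epoch + 1
        mse = _forward_mse(Xte, yte, W1, b1, w2, b2)
        if np.isnan(mse):
            nan_epoch = epoch + 1
            break
        if mse < best_mse:
            best_mse = mse
            best_epoch = epoch + 1
            bW1 = W1.copy()
            bb1 = b1.copy()
            bw2 = w2.copy()
            bb2 = b2
            since_best = 0
        else:
            since_best += 1
        if since_best >= patience:
            break
    return bW1, bb1, bw2, bb2, best_mse, epochs_run, best_epoch, nan_epoch


def _check_unit_interval(arr: np.ndarray, what: str) -> None:
    if not np.isfinite(arr).all():
        raise DataError(f"{what} contains non-finite values")
    if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
        raise DataError(f"{what} must lie in [0, 1]; scale inputs first")


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    split: DataSplit,
    config: TrainingConfig,
) -> TrainedMLP:
    """Train the perceptron on one MCCV split.

    Parameters
    ----------
    X
        Inputs, shape (n_features, n_samples), values in [0, 1].
    y
        Targets in [0, 1], shape (n_samples,).
    split
        Sample indices for the train / test / validation subsets.
    config
        Trainer hyper-parameters; ``config.seed`` drives weight
        initialisation (uniform in [-0.5, 0.5]) and per-epoch shuffling.

    Returns
    -------
    TrainedMLP
        Weights snapshotted at the best test MSE, with bookkeeping.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ShapeError("X must be 2-D (n_features, n_samples)")
    if y.shape[0] != X.shape[1]:
        raise ShapeError(
            f"y has {y.shape[0]} targets for {X.shape[1]} samples"
        )
    _check_unit_interval(X, "X")
    _check_unit_interval(y, "y")
    n_samples = X.shape[1]
    for name, idx in (
        ("train", split.train_idx),
        ("test", split.test_idx),
    ):
        if len(idx) == 0:
            raise SplitError(f"{name} subset is empty")
    all_idx = np.concatenate(
        [split.train_idx, split.test_idx, split.validation_idx]
    )
    if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= n_samples):
        raise SplitError("split indices out of range")

    samples = np.ascontiguousarray(X.T)  # (n_samples, n_features)
    Xtr = samples[split.train_idx]
    ytr = y[split.train_idx]
    Xte = samples[split.test_idx]
    yte = y[split.test_idx]

    rng = np.random.default_rng(config.seed)
    n_in = X.shape[0]
    W1 = rng.uniform(-0.5, 0.5, size=(n_in, config.n_hidden))
    b1 = rng.uniform(-0.5, 0.5, size=config.n_hidden)
    w2 = rng.uniform(-0.5, 0.5, size=config.n_hidden)
    b2 = float(rng.uniform(-0.5, 0.5))
    perms = np.empty((config.max_epochs, Xtr.shape[0]), dtype=np.int64)
    for e in range(config.max_epochs):
        perms[e] = rng.permutation(Xtr.shape[0])

    bW1, bb1, bw2, bb2, best_mse, epochs_run, best_epoch, nan_epoch = _train_kernel(
        Xtr,
        ytr,
        Xte,
        yte,
        W1,
        b1,
        w2,
        b2,
        float(config.learning_rate),
        float(config.momentum),
        int(config.max_epochs),
        int(config.patience_epochs),
        perms,
    )
    if nan_epoch >= 0:
        raise NumericalError(f"training loss became NaN at epoch {nan_epoch}")

    model = TrainedMLP(
        w_in_hidden=bW1,
        b_hidden=bb1,
        w_hidden_out=bw2,
        b_out=float(bb2),
        best_test_mse=float(best_mse),
        epochs_run=int(epochs_run),
        snapshot_epoch=int(best_epoch),
        seed=config.seed,
    )
    if len(split.validation_idx):
        Xval = samples[split.validation_idx]
        yval = y[split.validation_idx]
        model.validation_mse = float(evaluate_mse(model, Xval.T, yval))
    return model


def predict(model: TrainedMLP, X: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid(hidden) then sigmoid(output), outputs in (0, 1).

    ``X`` has shape (n_features, n_samples); returns one output per sample.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != model.n_inputs:
        raise ShapeError(
            f"model expects {model.n_inputs} inputs, got {X.shape[0]}"
        )
    hidden = 1.0 / (1.0 + np.exp(-(X.T @ model.w_in_hidden + model.b_hidden)))
    out = 1.0 / (1.0 + np.exp(-(hidden @ model.w_hidden_out + model.b_out)))
    return out


def evaluate_mse(model: TrainedMLP, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of the model's predictions against targets."""
    return float(np.mean((predict(model, X) - np.asarray(y, float).ravel()) ** 2))


def sample_gradients(
    W1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: float,
    x: np.ndarray,
    y: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradients of the per-sample loss (o - y)^2.

    Returns (dW1, db1, dw2, db2) — the quantities the trainer multiplies by
    the learning rate. Exposed so the update rule can be checked against
    finite differences.
    """
    x = np.asarray(x, dtype=float)
    hidden = 1.0 / (1.0 + np.exp(-(x @ W1 + b1)))
    o = float(1.0 / (1.0 + np.exp(-(hidden @ w2 + b2))))
    delta_o = 2.0 * (o - y) * o * (1.0 - o)
    dw2 = delta_o * hidden
    db2 = delta_o
    delta_h = delta_o * w2 * hidden * (1.0 - hidden)
    dW1 = np.outer(x, delta_h)
    db1 = delta_h
    return dW1, db1, dw2, db2
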