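"""Training recipe and evaluation driver.

Mini-batch SGD with momentum 0.9 and weight decay 1e-4, initial learning
rate 1e-3 stepped down by 10× after every 30 epochs, cross-entropy on the
raw two-way scores.  Inputs are standardized per channel by the training
split's mean/sd (stored with the history so evaluation matches).  Everything
is seeded: shuffling, dropout and weight initialization all derive from the
config seed, so two runs with the same seed produce identical histories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .metrics import confusion, metrics_from_counts, roc_auc
from .model import SeedSortNet
from .synthetic import LabeledImageSet, to_input_batch

__all__ = ["TrainConfig", "lr_at_epoch", "train", "predict", "evaluate",
           "softmax", "cross_entropy"]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_epoch: int = 30
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 100
    batch_size: int = 16
    rng_seed: int = 0
    stop_at_train_accuracy: float | None = None

    def __post_init__(self):
        if min(self.initial_lr, self.lr_decay_factor, self.momentum + 1,
               self.weight_decay + 1) <= 0 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr × factor^(number of completed decay periods).

    Epochs are 1-based; with the defaults epochs 1–30 run at 1e-3 and
    epoch 31 onward at 1e-4.
    """
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    steps = (epoch - 1) // config.lr_decay_epoch
    return config.initial_lr * config.lr_decay_factor ** steps


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of raw scores and its gradient w.r.t. the scores."""
    n = len(labels)
    probs = softmax(scores)
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class _SGD:
    def __init__(self, params, config: TrainConfig):
        self.params = params
        self.config = config
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        cfg = self.config
        for p, v in zip(self.params, self.velocity):
            g = p.grad + cfg.weight_decay * p.data
            v *= cfg.momentum
            v += g
            p.data = (p.data - lr * v).astype(p.data.dtype)


@dataclass
class TrainResult:
    network: SeedSortNet
    history: list = field(default_factory=list)  # dicts: epoch, lr, train_loss, train_acc, test_acc
    normalization: tuple = ((0.0,) * 3, (1.0,) * 3)

    def history_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "lr", "train_loss", "train_acc", "batch_acc", "test_acc"])
            writer.writeheader()
            writer.writerows(self.history)


def _standardize(x: np.ndarray, mean, sd) -> np.ndarray:
    mean = np.asarray(mean, dtype=np.float32)
    sd = np.asarray(sd, dtype=np.float32)
    return (x - mean) / sd


def train(network: SeedSortNet, train_set: LabeledImageSet,
          config: TrainConfig | None = None,
          test_set: LabeledImageSet | None = None,
          input_size: int | None = None) -> TrainResult:
    """Fit the network; returns the trained network plus per-epoch history."""
    config = config or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training split")
    size = input_size or train_set.images.shape[1]
    x = to_input_batch(train_set, size)
    y = train_set.labels.astype(np.int64)
    mean = x.mean(axis=(0, 1, 2))
    sd = x.std(axis=(0, 1, 2)) + 1e-6
    x = _standardize(x, mean, sd)
    x_test = y_test = None
    if test_set is not None and len(test_set):
        x_test = _standardize(to_input_batch(test_set, size), mean, sd)
        y_test = test_set.labels.astype(np.int64)

    rng = np.random.default_rng(config.rng_seed)
    optimizer = _SGD(network.parameters(), config)
    result = TrainResult(network=network,
                         normalization=(tuple(map(float, mean)), tuple(map(float, sd))))
    n = len(y)
    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            network.zero_grad()
            scores = network.forward(xb, training=True)
            loss, grad = cross_entropy(scores, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (lr={lr}); aborting")
            network.backward(grad.astype(np.float32))
            optimizer.step(lr)
            losses.append(loss)
            correct += int((scores.argmax(axis=1) == yb).sum())
        # epoch-end train accuracy in evaluation mode (dropout off, running
        # BN statistics) — the quantity early stopping and history report
        train_acc = float(
            (_predict_scores(network, x).argmax(axis=1) == y).mean())
        entry = {"epoch": epoch, "lr": lr,
                 "train_loss": float(np.mean(losses)), "train_acc": train_acc,
                 "batch_acc": correct / n, "test_acc": float("nan")}
        if x_test is not None:
            preds = _predict_scores(network, x_test).argmax(axis=1)
            entry["test_acc"] = float((preds == y_test).mean())
        result.history.append(entry)
        if (config.stop_at_train_accuracy is not None
                and train_acc >= config.stop_at_train_accuracy):
            break
    return result


def _predict_scores(network: SeedSortNet, x: np.ndarray,
                    batch_size: int = 32) -> np.ndarray:
    out = []
    for start in range(0, len(x), batch_size):
        out.append(network.forward(x[start:start + batch_size], training=False))
    return np.concatenate(out)


def predict(network: SeedSortNet, dataset: LabeledImageSet,
            normalization=None, input_size: int | None = None) -> np.ndarray:
    """Class-probability matrix for a dataset (softmax over raw scores)."""
    size = input_size or dataset.images.shape[1]
    x = to_input_batch(dataset, size)
    if normalization is not None:
        x = _standardize(x, *normalization)
    return softmax(_predict_scores(network, x))


def evaluate(network: SeedSortNet, dataset: LabeledImageSet,
             normalization=None, input_size: int | None = None):
    """Full metric report (Acc/p/r/F1 + ROC/AUC) on a labeled dataset."""
    probs = predict(network, dataset, normalization, input_size)
    preds = probs.argmax(axis=1)
    counts = confusion(preds, dataset.labels)
    report = metrics_from_counts(counts)
    roc = roc_auc(probs[:, 1], dataset.labels)
    report.auc = roc.auc
    report.roc = roc.roc
    return counts, report
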