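"""SGDM training of a realized network and the validation-error objective.

The optimizer is stochastic gradient descent with momentum,

    beta_{i+1} = beta_i - sigma * grad L(beta_i) + M * (beta_i - beta_{i-1}),

implemented in the equivalent velocity form (v <- M v - sigma grad;
beta <- beta + v).  The loss is cross-entropy plus an L2 penalty
``epsilon * 0.5 * ||w||^2`` on convolution and fully-connected weights
(biases and batch-norm parameters are exempt).  The learning rate decays
piecewise: a factor of ``lr_drop_factor`` every ``lr_drop_period`` epochs.

The quantity consumed by the Bayesian optimizer is the classification
error rate on the validation set, ``1 - mean validation accuracy``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .architecture import LayerPlan
from .network import Network, realize_network

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "DivergenceError",
    "lr_schedule",
    "sgdm_step",
    "regularized_loss",
    "train_network",
    "evaluate_objective",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainingConfig:
    """SGDM settings: step size, momentum, penalty and schedule."""

    initial_learning_rate: float = 0.01
    momentum: float = 0.9
    regularization: float = 0.0
    batch_size: int = 128
    max_epochs: int = 150
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 40
    bn_decay: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be positive")
        if not 0.0 < self.lr_drop_factor < 1.0:
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if self.regularization < 0:
            raise ValueError("regularization must be non-negative")


@dataclass
class TrainingHistory:
    """Per-epoch records of loss, accuracy and the learning rate in effect."""

    epoch: list[int] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"]
            )
            for row in zip(
                self.epoch,
                self.learning_rate,
                self.train_loss,
                self.train_accuracy,
                self.val_loss,
                self.val_accuracy,
            ):
                w.writerow(row)


def lr_schedule(epoch: int, config: TrainingConfig) -> float:
    """Learning rate in effect during ``epoch`` (1-based).

    sigma * factor^floor((epoch - 1) / period): epochs 1..period use sigma,
    the next ``period`` epochs use ``factor * sigma``, and so on.
    """
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    drops = (epoch - 1) // config.lr_drop_period
    return config.initial_learning_rate * config.lr_drop_factor**drops


def sgdm_step(params, gradient, previous_params, lr: float, momentum: float):
    """Two-point momentum update.

    beta_{i+1} = beta_i - lr * grad + momentum * (beta_i - beta_{i-1});
    with momentum 0 this is a plain gradient-descent step.
    """
    params = np.asarray(params, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    previous_params = np.asarray(previous_params, dtype=float)
    if not params.shape == gradient.shape == previous_params.shape:
        raise ValueError("params, gradient and previous_params must share a shape")
    return params - lr * gradient + momentum * (params - previous_params)


def regularized_loss(data_loss: float, weights, regularization: float) -> float:
    """L(beta) + epsilon * 0.5 * w^T w over the penalized weight vector."""
    w = np.asarray(weights, dtype=float).ravel()
    return float(data_loss) + regularization * 0.5 * float(w @ w)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) tuples; X is (N, C, H, W) float, y integer labels."""
    X, y = dataset
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("image and label counts differ")
    if X.shape[0] == 0:
        raise ValueError("empty dataset partition")
    return X, y


def _eval_loss_acc(net: Network, X, y, batch_size=256) -> tuple[float, float]:
    losses, correct = [], 0
    eps = np.finfo(np.float32).tiny
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        probs = net.predict_proba(xb, batch_size=batch_size)
        losses.append(-np.log(probs[np.arange(len(yb)), yb] + eps))
        correct += int(np.sum(probs.argmax(axis=1) == yb))
    return float(np.mean(np.concatenate(losses))), correct / X.shape[0]


def train_network(
    plan: LayerPlan,
    train_set,
    val_set,
    config: TrainingConfig,
) -> tuple[Network, TrainingHistory]:
    """Mini-batch SGDM training of a freshly initialized network.

    ``train_set`` / ``val_set`` are ``(images, labels)`` pairs with images
    shaped ``(N, C, H, W)``.  Each epoch reshuffles the training set with
    the seeded generator; batch-norm running statistics are updated with
    ``config.bn_decay``.  Returns the final-epoch model and its history.

    Raises :class:`DivergenceError` (with the offending epoch) when the
    loss becomes non-finite.
    """
    Xtr, ytr = _as_arrays(train_set)
    Xval, yval = _as_arrays(val_set)
    rng = np.random.default_rng(config.seed)
    net = realize_network(plan, rng=rng, bn_decay=config.bn_decay)

    velocity = {
        key: np.zeros_like(arr) for key, _, _, arr in net.named_parameters()
    }
    history = TrainingHistory()
    n = Xtr.shape[0]

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        epoch_losses, epoch_accs, epoch_sizes = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, acc = net.loss_and_gradients(
                Xtr[idx], ytr[idx], regularization=config.regularization
            )
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            for key, layer, name, arr in net.named_parameters():
                v = velocity[key]
                v *= config.momentum
                v -= lr * layer.grads[name]
                layer.params[name] = arr + v
                velocity[key] = v
            epoch_losses.append(loss)
            epoch_accs.append(acc)
            epoch_sizes.append(len(idx))

        wts = np.array(epoch_sizes, dtype=float)
        train_loss = float(np.average(epoch_losses, weights=wts))
        train_acc = float(np.average(epoch_accs, weights=wts))
        val_loss, val_acc = _eval_loss_acc(net, Xval, yval)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history.epoch.append(epoch)
        history.learning_rate.append(lr)
        history.train_loss.append(train_loss)
        history.train_accuracy.append(train_acc)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

    # population batch-norm statistics for inference (full training pass)
    net.finalize_bn_statistics(Xtr, batch_size=config.batch_size)
    return net, history


def evaluate_objective(model: Network, val_set) -> float:
    """Validation classification error rate: 1 - fraction correct."""
    X, y = _as_arrays(val_set)
    predictions = model.predict(X)
    return 1.0 - float(np.mean(predictions == y))


def save_model(model: Network, path) -> None:
    """Serialize weights + batch-norm statistics as an .npz archive."""
    np.savez(path, **model.state_dict())


def load_model(plan: LayerPlan, path) -> Network:
    """Rebuild a network from a plan and a saved .npz state."""
    net = realize_network(plan, rng=0)
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
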