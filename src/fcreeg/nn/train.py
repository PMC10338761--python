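"""Training loop: Adam, step learning-rate decay, early stopping.

Defaults follow the study protocol: Adam with initial learning rate
0.001 multiplied by 0.4 every 4 epochs, mini-batches of 32, at most 15
epochs, early stopping on validation loss (patience 3, best weights
restored).  "Decreased by 0.4" is a multiplicative step decay —
subtracting 0.4 from 0.001 would go negative immediately.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Module, Param


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    lr_factor: float = 0.4       # multiplicative decay ...
    lr_step_epochs: int = 4      # ... applied every 4 epochs
    batch_size: int = 32
    max_epochs: int = 15
    patience: int = 3            # early stopping on validation loss
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")
        for name in ("initial_lr", "batch_size", "max_epochs", "lr_step_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def _snapshot(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: Module, state: list[np.ndarray]) -> None:
    for p, s in zip(model.parameters(), state):
        p.data[...] = s


def evaluate(model: Module, x: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> tuple[float, float]:
    """(mean loss, accuracy fraction) in eval mode."""
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model(x[i:i + batch_size])
        loss, _ = cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict_proba(model: Module, x: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = [softmax(model(x[i:i + batch_size]))
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def fit(model: Module, x_train: np.ndarray, y_train: np.ndarray,
        x_val: np.ndarray, y_val: np.ndarray,
        cfg: TrainConfig | None = None) -> dict:
    """Train with early stopping; returns the per-epoch history.

    History keys: train_loss, train_acc, val_loss, val_acc, lr; also
    best_epoch (the restored weights' epoch).
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    history = {k: [] for k in ("train_loss", "train_acc", "val_loss",
                               "val_acc", "lr")}
    best_loss, best_state, best_epoch, bad = np.inf, _snapshot(model), 0, 0
    n = len(x_train)
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.initial_lr * cfg.lr_factor ** (epoch // cfg.lr_step_epochs)
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model(xb)
            loss, gl = cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(gl)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = evaluate(model, x_val, y_val)
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, best_epoch, bad = \
                val_loss, _snapshot(model), epoch, 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    _restore(model, best_state)
    history["best_epoch"] = best_epoch
    return history
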