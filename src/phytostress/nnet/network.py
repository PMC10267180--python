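"""Network container, loss, optimizer and the training loop."""

from __future__ import annotations

import time

import numpy as np

from .layers import Layer, Param


def softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward stack of layers operating on (batch, 1, time) input."""

    def __init__(self, layers: list[Layer], input_length: int, n_classes: int = 2):
        self.layers = layers
        self.input_length = input_length
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.input_length:
            raise ValueError(
                f"input has {x.shape[2]} samples per window, model expects {self.input_length}"
            )
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, dropout off; batching never changes values."""
        out = []
        for s in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[s : s + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cross_entropy(logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None):
    """Mean weighted cross-entropy; returns (loss, dlogits)."""
    n = len(y)
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[y]
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), y] + eps)).sum() / w.sum())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    d *= (w / w.sum())[:, None]
    return loss, d


def train_network(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    seed: int,
    batch_size: int = 64,
    lr: float = 1e-3,
    class_weights: np.ndarray | None = None,
    max_seconds: float | None = None,
) -> dict:
    """Seeded mini-batch Adam training; returns a manifest of the run."""
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr)
    y = np.asarray(y, dtype=np.int64)
    losses: list[float] = []
    t_start = time.perf_counter()
    epochs_done = 0
    for _ in range(epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, len(x), batch_size):
            idx = order[s : s + batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], train=True, rng=rng)
            loss, d = cross_entropy(logits, y[idx], class_weights)
            net.backward(d)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        epochs_done += 1
        if max_seconds is not None and time.perf_counter() - t_start > max_seconds:
            break
    return {
        "epochs_requested": epochs,
        "epochs_completed": epochs_done,
        "batch_size": batch_size,
        "learning_rate": lr,
        "seed": seed,
        "losses": losses,
        "wall_seconds": time.perf_counter() - t_start,
    }
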