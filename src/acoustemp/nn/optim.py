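"""AdamW, cosine-annealing schedule and the MSE loss."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "cosine_annealing_lr", "mse_loss"]


def cosine_annealing_lr(
    epoch: float, total_epochs: int, lr_init: float, lr_final: float
) -> float:
    """lr(e) = lr_final + (lr_init - lr_final) * (1 + cos(pi * e / E)) / 2."""
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    return lr_final + (lr_init - lr_final) * (1.0 + np.cos(np.pi * epoch / total_epochs)) / 2.0


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch between predictions and targets")
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is skipped for parameters flagged ``weight_decay=False``
    (biases and normalisation scales/offsets).
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.weight_decay and self.weight_decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
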