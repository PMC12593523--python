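"""Optimizers and loss helpers for the numpy network stack."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "cross_entropy"]


class Adam:
    """Adam with bias-corrected first/second moments (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax logits.

    Custom op with the analytic gradient ``(softmax - onehot)/N``.
    """
    labels = np.asarray(labels, dtype=int)
    z = logits.data - np.max(logits.data, axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / np.sum(ez, axis=1, keepdims=True)
    n = labels.size
    nll = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    out = Tensor(np.asarray(nll, dtype=logits.data.dtype), parents=(logits,))

    def bw(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate((g * grad / n).astype(logits.data.dtype))

    out._backward = bw
    return out
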