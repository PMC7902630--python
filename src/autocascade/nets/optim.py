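"""Adam optimiser and the binary cross-entropy objective."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Standard Adam (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_from_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-voxel binary cross entropy and its gradient w.r.t. logits.

    Computed from logits with the log-sum-exp form for numerical stability;
    the gradient is (sigmoid(z) - y) / n_voxels.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    probs = 1.0 / (1.0 + np.exp(-z))
    dlogits = ((probs - y) / z.size).astype(np.float32)
    return loss, dlogits
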