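"""Adam optimizer and multistep learning-rate schedule."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .autodiff import Tensor


class Adam:
    """Adam with bias-corrected first and second moments."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-2,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params: List[Tensor] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MultiStepLR:
    """Multiply the optimizer's learning rate by ``gamma`` at each milestone epoch."""

    def __init__(self, optimizer: Adam, milestones: Sequence[int], gamma: float = 0.1):
        self.optimizer = optimizer
        self.milestones = sorted(int(m) for m in milestones)
        self.gamma = gamma
        self.base_lr = optimizer.lr
        self.epoch = 0

    def lr_at(self, epoch: int) -> float:
        n_passed = sum(1 for m in self.milestones if epoch >= m)
        return self.base_lr * self.gamma**n_passed

    def step(self) -> None:
        """Advance one epoch and update the optimizer's learning rate."""
        self.epoch += 1
        self.optimizer.lr = self.lr_at(self.epoch)
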