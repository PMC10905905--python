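"""Adam optimizer over named parameter tensors.

Weight decay is the coupled L2 form (decay added to the gradient before the
moment updates), matching the convention of the deep-learning framework the
training recipes were specified in.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor


class Adam:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.value) for k, t in params.items()}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
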