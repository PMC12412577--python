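"""Adam optimizer over a named parameter store."""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        names: Optional[Iterable[str]] = None,
    ):
        self.params = params
        self.names = list(names) if names is not None else list(params.keys())
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(params[k].data, dtype=np.float64) for k in self.names}
        self.v = {k: np.zeros_like(params[k].data, dtype=np.float64) for k in self.names}

    def zero_grad(self) -> None:
        for k in self.names:
            self.params[k].grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k in self.names:
            p = self.params[k]
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype, copy=False
            )
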