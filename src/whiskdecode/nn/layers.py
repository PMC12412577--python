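"""Layer primitives assembled from autodiff Tensors.

Parameters live in a flat ``dict[str, Tensor]`` owned by the model, so that
serialization, hashing and optimizer state can address every parameter by
name.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["ParamStore", "dense", "lstm", "init_dense", "init_lstm"]

ParamStore = Dict[str, Tensor]


def _uniform(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


def init_dense(params: ParamStore, name: str, n_in: int, n_out: int, rng: np.random.Generator) -> None:
    scale = 1.0 / np.sqrt(n_in)
    params[f"{name}.W"] = Tensor(_uniform(rng, (n_in, n_out), scale), requires_grad=True)
    params[f"{name}.b"] = Tensor(np.zeros(n_out), requires_grad=True)


def dense(params: ParamStore, name: str, x: Tensor) -> Tensor:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def init_lstm(params: ParamStore, name: str, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
    scale = 1.0 / np.sqrt(max(n_in, n_hidden))
    params[f"{name}.Wx"] = Tensor(_uniform(rng, (n_in, 4 * n_hidden), scale), requires_grad=True)
    params[f"{name}.Wh"] = Tensor(_uniform(rng, (n_hidden, 4 * n_hidden), scale), requires_grad=True)
    b = np.zeros(4 * n_hidden)
    b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias: remember by default
    params[f"{name}.b"] = Tensor(b, requires_grad=True)


def lstm(params: ParamStore, name: str, x_seq: Tensor) -> Tensor:
    """Unidirectional LSTM over (B, T, D); returns the final hidden state (B, H).

    Gate order in the packed weight matrices: input, forget, cell, output.
    """
    Wx, Wh, b = params[f"{name}.Wx"], params[f"{name}.Wh"], params[f"{name}.b"]
    B, T, D = x_seq.shape
    H = Wh.shape[0]
    h = Tensor(np.zeros((B, H), dtype=x_seq.data.dtype))
    c = Tensor(np.zeros((B, H), dtype=x_seq.data.dtype))
    for t in range(T):
        x_t = x_seq[:, t, :]
        gates = x_t @ Wx + h @ Wh + b
        i = gates[:, 0:H].sigmoid()
        f = gates[:, H : 2 * H].sigmoid()
        g = gates[:, 2 * H : 3 * H].tanh()
        o = gates[:, 3 * H : 4 * H].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
    return h
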