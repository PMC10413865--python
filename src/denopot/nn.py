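"""Parameter containers, MLPs, AdamW, and the warmup+cosine LR schedule."""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameters",
    "init_linear",
    "init_mlp",
    "mlp_forward",
    "AdamW",
    "warmup_cosine_lr",
]


class Parameters(dict):
    """Flat name → Tensor mapping with convenience constructors.

    All parameter tensors have ``requires_grad=True``; values are float64.
    """

    def tensors(self) -> list[Tensor]:
        return list(self.values())

    def astype(self, dtype) -> None:
        """In-place dtype conversion of all parameter arrays."""
        for v in self.values():
            v.data = v.data.astype(dtype)

    def copy_values(self) -> "Parameters":
        out = Parameters()
        for k, v in self.items():
            t = Tensor(v.data.copy())
            t.requires_grad = True
            out[k] = t
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.items():
            if k not in arrays:
                raise KeyError(f"missing parameter {k!r}")
            if arrays[k].shape != v.data.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {arrays[k].shape} vs {v.data.shape}"
                )
            v.data = np.asarray(arrays[k], dtype=np.float64).copy()

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.items()}


def _param(data: np.ndarray) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True
    return t


def init_linear(
    params: Parameters,
    name: str,
    fan_in: int,
    fan_out: int,
    rng: np.random.Generator,
    zero: bool = False,
) -> None:
    if zero:
        w = np.zeros((fan_in, fan_out))
    else:
        w = rng.normal(0.0, math.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
    params[f"{name}.w"] = _param(w)
    params[f"{name}.b"] = _param(np.zeros(fan_out))


def linear_forward(params: Parameters, name: str, x: Tensor) -> Tensor:
    return x @ params[f"{name}.w"] + params[f"{name}.b"]


def init_mlp(
    params: Parameters,
    name: str,
    dims: list[int],
    rng: np.random.Generator,
    zero_last: bool = False,
) -> None:
    """Register weights for an MLP with layer widths ``dims``."""
    for i in range(len(dims) - 1):
        last = i == len(dims) - 2
        init_linear(
            params, f"{name}.{i}", dims[i], dims[i + 1], rng, zero=zero_last and last
        )


def mlp_forward(
    params: Parameters,
    name: str,
    x: Tensor,
    n_layers: int,
    activation: Callable[[Tensor], Tensor] = ad.silu,
) -> Tensor:
    for i in range(n_layers):
        x = linear_forward(params, f"{name}.{i}", x)
        if i < n_layers - 1:
            x = activation(x)
    return x


def warmup_cosine_lr(step: int, total_steps: int, max_lr: float, warmup_fraction: float) -> float:
    """Linear warmup to ``max_lr`` then cosine decay to zero."""
    warmup = max(1, int(round(warmup_fraction * total_steps)))
    if step < warmup:
        return max_lr * (step + 1) / warmup
    if total_steps <= warmup:
        return max_lr
    progress = (step - warmup) / (total_steps - warmup)
    return 0.5 * max_lr * (1.0 + math.cos(math.pi * progress))


class AdamW:
    """Decoupled-weight-decay Adam over a :class:`Parameters` dict."""

    def __init__(
        self,
        params: Parameters,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        clip_norm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
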