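"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2d, conv2d

__all__ = ["Module", "Conv2d", "Linear", "softmax", "l2_distance"]


class Module:
    """Base class: tracks parameters, supports state export/import."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax (shift by detached row max)."""
    shift = logits.data.max(axis=axis, keepdims=True)
    e = (logits - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2_distance(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    """Plain (unsquared) L2 distance along ``axis`` (exact at zero)."""
    d = a - b
    return (d * d).sum(axis=axis).sqrt()


class RMSProp:
    """Root-mean-squared-propagation optimizer with conventional defaults."""

    def __init__(self, params, lr: float = 1e-4, alpha: float = 0.99,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.alpha
            c += (1.0 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# re-export pooling for convenience
__all__ += ["RMSProp", "avg_pool2d"]
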