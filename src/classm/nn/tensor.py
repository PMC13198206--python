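"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the classifier needs: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, reshaping,
row gather, 2-D convolution and 2x2 average pooling.  Gradients accumulate
into ``Tensor.grad`` after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "avg_pool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * np.power(self.data, p - 1),)

        return self._make(np.power(self.data, p), (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            # floor keeps the gradient bounded at 0 (subgradient of |x|
            # through sqrt(x^2) stays in [-1, 1]); forward stays exact
            return (g / (2.0 * np.maximum(out_data, 1e-6)),)

        return self._make(out_data, (self,), backward)

    # -- reductions / shape --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(g):
            if axes is None:
                return (g.T,)
            return (np.transpose(g, np.argsort(axes)),)

        return self._make(np.transpose(self.data, axes or None), (self,), backward)

    def take_rows(self, indices):
        """Gather rows along axis 0 (differentiable scatter-add backward)."""
        indices = np.asarray(indices, dtype=np.intp)

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, indices, g)
            return (gx,)

        return self._make(self.data[indices], (self,), backward)

    # -- autograd driver -----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf parameter/input
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = np.asarray(pg, dtype=np.float64)


# ---------------------------------------------------------------------------
# Convolution / pooling (custom forward+backward for efficiency)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(dcols, xshape, kh, kw, oh, ow, stride, pad):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp))
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); x (N,C,H,W), w (F,C,kh,kw)."""
    n = x.data.shape[0]
    f, c, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)  # (N, C*kh*kw, L)
    wf = w.data.reshape(f, -1)
    out_data = np.matmul(wf, cols)  # (N, F, L)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1)
    out_data = out_data.reshape(n, f, oh, ow)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(n, f, oh * ow)
        dw = np.einsum("nfl,nkl->fk", gf, cols, optimize=True).reshape(w.data.shape)
        dcols = np.matmul(wf.T, gf)  # (N, C*kh*kw, L)
        dx = _col2im(dcols, x.data.shape, kh, kw, oh, ow, stride, pad)
        if b is None:
            return (dx, dw)
        db = g.sum(axis=(0, 2, 3))
        return (dx, dw, db)

    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k average pooling with stride k (spatial dims divisible by k)."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        return (gx,)

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out
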