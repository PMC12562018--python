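"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the convolutional/recurrent
classifier stacks on CPU: tensors with a backward tape, broadcasting
arithmetic, matmul, 'same'-padded Conv2D via im2col, 2x2 max pooling,
the usual activations, dropout, and an Adam optimizer.  Everything is
float64 and fully deterministic given seeded numpy generators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "sigmoid", "tanh", "relu", "concat",
           "conv2d", "maxpool2x2", "dropout", "bce_loss"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
        return self._make(self.data[key], (self,), backward)

    def sum(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        return self._make(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape).copy())
        return self._make(self.data.mean(), (self,), backward)


# -- activations and structural ops ----------------------------------------


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g):
        if t.requires_grad:
            t._accum(g * mask)
    return t._make(t.data * mask, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(t.data, -500, 500)))

    def backward(g):
        if t.requires_grad:
            t._accum(g * s * (1 - s))
    return t._make(s, (t,), backward)


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * (1 - y * y))
    return t._make(y, (t,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def dropout(t: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity at evaluation time."""
    if not training or rate <= 0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)

    def backward(g):
        if t.requires_grad:
            t._accum(g * mask)
    return t._make(t.data * mask, (t,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'same'-padded, stride-1 2-D convolution (cross-correlation, the
    deep-learning convention).

    ``x``: (N, H, W, C_in); ``w``: (kh, kw, C_in, C_out); ``b``: (C_out,).
    """
    N, H, W, Cin = x.data.shape
    kh, kw, _, Cout = w.data.shape
    ph0, ph1 = (kh - 1) // 2, kh - 1 - (kh - 1) // 2
    pw0, pw1 = (kw - 1) // 2, kw - 1 - (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    # im2col
    cols = np.empty((N, H, W, kh * kw * Cin))
    k = 0
    for di in range(kh):
        for dj in range(kw):
            cols[..., k * Cin:(k + 1) * Cin] = xp[:, di:di + H, dj:dj + W, :]
            k += 1
    wmat = w.data.reshape(kh * kw * Cin, Cout)
    out_data = cols @ wmat + b.data

    def backward(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = cols.reshape(-1, kh * kw * Cin).T @ g.reshape(-1, Cout)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = g @ wmat.T  # (N, H, W, kh*kw*Cin)
            gxp = np.zeros_like(xp)
            k = 0
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, di:di + H, dj:dj + W, :] += \
                        gcols[..., k * Cin:(k + 1) * Cin]
                    k += 1
            x._accum(gxp[:, ph0:ph0 + H, pw0:pw0 + W, :])
    out = x._make(out_data, (x, w, b), backward)
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    r = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    out_data = r.max(axis=(2, 4))
    mask = (r == out_data[:, :, None, :, None, :])

    def backward(g):
        if x.requires_grad:
            gr = mask * g[:, :, None, :, None, :]
            # if a window had tied maxima, split the gradient equally
            counts = mask.sum(axis=(2, 4), keepdims=True)
            gr = gr / counts
            x._accum(gr.reshape(N, H, W, C))
    return x._make(out_data, (x,), backward)


def bce_loss(p: Tensor, targets: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Binary cross-entropy of predicted probabilities against 0/1
    targets, averaged over the batch."""
    y = np.asarray(targets, dtype=np.float64).reshape(p.data.shape)
    pc = np.clip(p.data, eps, 1 - eps)
    loss_val = -(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean()

    def backward(g):
        if p.requires_grad:
            p._accum(g * (pc - y) / (pc * (1 - pc)) / y.size)
    return p._make(loss_val, (p,), backward)


class Adam:
    """Adam optimizer (defaults match the usual 0.9/0.999/1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
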