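"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package needs gradients in three places: training the convolutional
network, integrated-gradients attribution (gradients w.r.t. the input image)
and gradient-ascent optimization of single input channels. A small tape-based
engine covers all three. Only the operations the network uses are provided:
broadcasting arithmetic, matmul, a 2-D cross-correlation over a
(batch, channels, length, seq) layout, reductions, concatenation, slicing and
the activations.

Arrays are float32 by default; ``Tensor.backward`` accumulates float32
gradients into ``.grad`` for every tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    # float ndarrays keep their precision (float64 supported for exactness
    # tests and optimizer bookkeeping); everything else becomes float32
    if isinstance(x, np.ndarray) and np.issubdtype(x.dtype, np.floating):
        return x
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(DTYPE)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(mask * gg)

        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(res, (self,), bwd)

    # -- activations ------------------------------------------------------
    def relu(self):
        mask = (self.data > 0).astype(DTYPE)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def exp(self):
        e = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * e)

        return Tensor._make(e, (self,), bwd)


def concat(tensors: list, axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           pad_length: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (B, Cin, L, S) with ``weight`` (Cout, Cin, KL, KS).

    The length axis is zero-padded by ``pad_length`` on both sides; the seq
    axis is never padded, so a KS=2 kernel collapses S from 2 to 1. Implemented
    as im2col + matmul so BLAS carries the arithmetic.
    """
    B, Cin, L, S = x.data.shape
    Cout, Cin_w, KL, KS = weight.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    p = pad_length
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (0, 0))) if p else x.data
    Lo = L + 2 * p - KL + 1
    So = S - KS + 1
    if Lo < 1 or So < 1:
        raise ValueError("kernel larger than (padded) input")
    win = np.lib.stride_tricks.sliding_window_view(xp, (KL, KS), axis=(2, 3))
    # (B, Cin, Lo, So, KL, KS) -> (B*Lo*So, Cin*KL*KS)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Lo * So, Cin * KL * KS)
    Wm = weight.data.reshape(Cout, Cin * KL * KS)
    out = (cols @ Wm.T).reshape(B, Lo, So, Cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        # g: (B, Cout, Lo, So)
        gm = g.transpose(0, 2, 3, 1).reshape(B * Lo * So, Cout)
        if weight.requires_grad:
            dW = (gm.T @ cols).reshape(Cout, Cin, KL, KS)
            weight._accumulate(dW)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(KL):
                for j in range(KS):
                    # (B,Cout,Lo,So) x (Cout,Cin) -> (B,Cin,Lo,So)
                    contrib = np.einsum(
                        "bols,oc->bcls", g, weight.data[:, :, i, j], optimize=True
                    )
                    dxp[:, :, i : i + Lo, j : j + So] += contrib
            dx = dxp[:, :, p : p + L, :] if p else dxp
            x._accumulate(dx)

    return Tensor._make(out, parents, bwd)
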