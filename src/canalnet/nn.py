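"""Minimal reverse-mode automatic differentiation and neural-network layers.

The segmentation network in :mod:`canalnet.model` runs on CPU at miniature
problem sizes, so the whole engine is plain numpy: a :class:`Tensor` records
the computation graph, :func:`Tensor.backward` runs reverse-mode
accumulation, and layer classes (:class:`Conv2dTD`, :class:`Conv3d`,
:class:`BiConvLSTM`, :class:`BatchNorm`) hold parameters.  Convolutions are
im2col matrix products so the heavy lifting stays inside BLAS.

Array layout convention: feature maps are ``(T, C, H, W)`` with axis 0 the
slice ("temporal") axis of the volume and axis 1 the channel axis.  All
arithmetic is float64; everything is deterministic given the seeds handed to
the initialisers.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "relu",
    "sigmoid",
    "tanh",
    "amax",
    "maxpool2",
    "avgpool2",
    "upsample2",
    "Module",
    "Conv2dTD",
    "Conv3d",
    "BiConvLSTM",
    "BatchNorm",
    "Adam",
]


# ---------------------------------------------------------------------------
# Tensor and primitive operations
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth explodes on LSTM chains
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references so memory is reclaimed between steps
        for node in topo:
            node._parents = ()
            node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bwd
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full(self.data.shape, float(g)))

        out._backward = bwd
        return out

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Contiguous slice ``[start, start+length)`` along ``axis``."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        offset = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(offset, offset + n)
                t._accum(g[tuple(idx)])
            offset += n

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    out._backward = bwd
    return out


def amax(x: Tensor, axis: int) -> Tensor:
    """Maximum along one axis; gradient routes to the first argmax (ties)."""
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(idx, axis),
                                  axis=axis).squeeze(axis)
    out = Tensor(out_data, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            x._accum(full)

    out._backward = bwd
    return out


def mean_axes(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    """Mean over ``axes`` with keepdims (used by batch normalisation)."""
    x = as_tensor(x)
    n = int(np.prod([x.data.shape[a] for a in axes]))
    out = Tensor(x.data.mean(axis=axes, keepdims=True), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g / n, x.data.shape).copy())

    out._backward = bwd
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    r = np.sqrt(x.data)
    out = Tensor(r, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * 0.5 / r)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Pooling / resampling on (T, C, H, W) maps — 2x2x2 over (T, H, W)
# ---------------------------------------------------------------------------

def _windows8(data: np.ndarray) -> np.ndarray:
    """Reshape (T,C,H,W) into (T/2, C, H/2, W/2, 8) windows of 2x2x2 blocks."""
    T, C, H, W = data.shape
    r = data.reshape(T // 2, 2, C, H // 2, 2, W // 2, 2)
    return r.transpose(0, 2, 3, 5, 1, 4, 6).reshape(T // 2, C, H // 2, W // 2, 8)


def _unwindows8(win: np.ndarray, shape: tuple) -> np.ndarray:
    T, C, H, W = shape
    r = win.reshape(T // 2, C, H // 2, W // 2, 2, 2, 2)
    return r.transpose(0, 4, 1, 2, 5, 3, 6).reshape(T, C, H, W)


def _check_even(shape):
    T, _, H, W = shape
    if T % 2 or H % 2 or W % 2:
        raise ValueError(f"cannot 2x2x2-pool shape {shape}: T/H/W must be even")


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max-pooling over (slice, row, col); halves all three axes."""
    x = as_tensor(x)
    _check_even(x.data.shape)
    win = _windows8(x.data)
    idx = np.argmax(win, axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gwin = np.zeros_like(win)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            x._accum(_unwindows8(gwin, x.data.shape))

    out._backward = bwd
    return out


def avgpool2(x: Tensor) -> Tensor:
    """2x2x2 average-pooling over (slice, row, col)."""
    x = as_tensor(x)
    _check_even(x.data.shape)
    win = _windows8(x.data)
    out = Tensor(win.mean(axis=-1), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gwin = np.repeat(g[..., None] / 8.0, 8, axis=-1)
            x._accum(_unwindows8(gwin, x.data.shape))

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x up-sampling of (slice, row, col)."""
    x = as_tensor(x)
    d = np.repeat(np.repeat(np.repeat(x.data, 2, axis=0), 2, axis=2), 2, axis=3)
    out = Tensor(d, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            T, C, H, W = g.shape
            gg = g.reshape(T // 2, 2, C, H // 2, 2, W // 2, 2).sum(axis=(1, 4, 6))
            x._accum(gg)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolutions (im2col)
# ---------------------------------------------------------------------------

def _conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 2D convolution treating axis 0 as batch.

    x: (T, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,)
    """
    T, Cin, H, W = x.shape
    Cout, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (T,Cin,H,W,k,k)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(T * H * W, Cin * k * k)
    y = cols @ w.reshape(Cout, -1).T + b
    return y.reshape(T, H, W, Cout).transpose(0, 3, 1, 2), cols


def _conv2d_backward(g: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    T, Cin, H, W = x_shape
    Cout, _, k, _ = w.shape
    p = k // 2
    gmat = g.transpose(0, 2, 3, 1).reshape(T * H * W, Cout)
    gw = (gmat.T @ cols).reshape(w.shape)
    gb = gmat.sum(axis=0)
    gcols = (gmat @ w.reshape(Cout, -1)).reshape(T, H, W, Cin, k, k)
    gx = np.zeros((T, Cin, H + 2 * p, W + 2 * p))
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + H, j:j + W] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return gx[:, :, p:p + H, p:p + W], gw, gb


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    y, cols = _conv2d_forward(x.data, w.data, b.data)
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        gx, gw, gb = _conv2d_backward(g, cols, x.data.shape, w.data)
        if x.requires_grad:
            x._accum(gx)
        if w.requires_grad:
            w._accum(gw)
        if b.requires_grad:
            b._accum(gb)

    out._backward = bwd
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded volumetric convolution; x: (T,Cin,H,W), w: (Cout,Cin,k,k,k)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    T, Cin, H, W = x.data.shape
    Cout, _, k, _, _ = w.data.shape
    p = k // 2
    xp = np.pad(x.data.transpose(1, 0, 2, 3), ((0, 0), (p, p), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (Cin,T,H,W,k,k,k)
    cols = cols.transpose(1, 2, 3, 0, 4, 5, 6).reshape(T * H * W, Cin * k ** 3)
    y = cols @ w.data.reshape(Cout, -1).T + b.data
    out = Tensor(y.reshape(T, H, W, Cout).transpose(0, 3, 1, 2), parents=(x, w, b))

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(T * H * W, Cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ w.data.reshape(Cout, -1)).reshape(T, H, W, Cin, k, k, k)
            gx = np.zeros((Cin, T + 2 * p, H + 2 * p, W + 2 * p))
            for a in range(k):
                for i in range(k):
                    for j in range(k):
                        gx[:, a:a + T, i:i + H, j:j + W] += \
                            gcols[:, :, :, :, a, i, j].transpose(3, 0, 1, 2)
            x._accum(gx[:, p:p + T, p:p + H, p:p + W].transpose(1, 0, 2, 3))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Parameter container with torch-like ``parameters()`` recursion."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def named_modules(self, prefix: str = "") -> Iterable[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_modules(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{key}.{i}.")

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.training = flag


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2dTD(Module):
    """Time-distributed same-padded 2D convolution (applied per slice)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Conv3d(Module):
    """Same-padded volumetric convolution over (slice, row, col)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = in_ch * kernel ** 3
        self.weight = Tensor(
            _he_uniform(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class BatchNorm(Module):
    """Per-channel normalisation over (slice, row, col) of a (T,C,H,W) map.

    Training mode uses batch statistics and maintains an exponential moving
    average; inference mode applies the stored running statistics, giving
    bit-identical repeated forward passes.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = mean_axes(x, (0, 2, 3))
            var = mean_axes((x - mu) * (x - mu), (0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) / sqrt(var + self.eps)
        else:
            xhat = (x - Tensor(self.running_mean)) / sqrt(
                Tensor(self.running_var) + self.eps)
        return self.gamma * xhat + self.beta


class ConvLSTMCell(Module):
    """Convolutional LSTM gate set with 3x3 in-plane kernels."""

    def __init__(self, in_ch: int, hidden: int, kernel: int, rng: np.random.Generator):
        self.hidden = hidden
        self.gates = Conv2dTD(in_ch + hidden, 4 * hidden, kernel, rng)
        # forget gate opens at init (bias 1): standard LSTM practice so early
        # gradients propagate along the slice axis
        self.gates.bias.data[hidden:2 * hidden] = 1.0

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = self.gates(concat([x_t, h], axis=1))
        hs = self.hidden
        i = sigmoid(z.narrow(1, 0, hs))
        f = sigmoid(z.narrow(1, hs, hs))
        o = sigmoid(z.narrow(1, 2 * hs, hs))
        g = tanh(z.narrow(1, 3 * hs, hs))
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new


class BiConvLSTM(Module):
    """Bidirectional ConvLSTM along the slice axis.

    Runs independent forward and backward recurrences and concatenates their
    hidden sequences on the channel axis, so the output has ``2 * hidden``
    channels and the same (T, H, W) extent as the input.
    """

    def __init__(self, in_ch: int, hidden: int, kernel: int, rng: np.random.Generator):
        self.fwd = ConvLSTMCell(in_ch, hidden, kernel, rng)
        self.bwd = ConvLSTMCell(in_ch, hidden, kernel, rng)
        self.hidden = hidden

    def _run(self, cell: ConvLSTMCell, x: Tensor, order: range) -> list[Tensor]:
        _, _, H, W = x.data.shape
        h = Tensor(np.zeros((1, cell.hidden, H, W)))
        c = Tensor(np.zeros((1, cell.hidden, H, W)))
        outs: dict[int, Tensor] = {}
        for t in order:
            h, c = cell.step(x.narrow(0, t, 1), h, c)
            outs[t] = h
        return [outs[t] for t in range(x.data.shape[0])]

    def __call__(self, x: Tensor) -> Tensor:
        T = x.data.shape[0]
        fw = self._run(self.fwd, x, range(T))
        bw = self._run(self.bwd, x, range(T - 1, -1, -1))
        per_t = [concat([fw[t], bw[t]], axis=1) for t in range(T)]
        return concat(per_t, axis=0)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2.5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
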