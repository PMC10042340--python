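"""Minimal reverse-mode autodiff on NumPy arrays.

Just enough machinery for the boundary-detection network: vertical
(k x 1) convolutions with dilation, ReLU, 2x2 max-pooling, nearest
2x upsampling, channel concatenation, elementwise sum, and a fused
depth-axis softmax / cross-entropy loss.  Everything is float32 and
single-threaded-deterministic (pure NumPy, no atomics).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv2d_vert",
    "relu",
    "maxpool2x2",
    "upsample2x2",
    "concat_channels",
    "add",
    "softmax_depth_xent",
    "AMSGrad",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, parents: tuple["Tensor", ...] = ()):
        arr = np.asarray(data, dtype=np.float32)
        if arr.ndim and not arr.flags["C_CONTIGUOUS"]:
            arr = np.ascontiguousarray(arr)
        self.data = arr
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] = lambda: None
        self._parents = parents

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()


def conv2d_vert(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Vertical (K x 1) convolution with 'same' padding along depth.

    x: (N, C, H, W); w: (O, C, K); b: (O,).  The kernel slides only
    along the depth (H) axis; K must be odd so output height == H.
    """
    n, c, h, wd = x.data.shape
    o, c2, k = w.data.shape
    if c2 != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    if k % 2 != 1:
        raise ValueError("kernel height must be odd")
    pad = dilation * (k // 2)
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (0, 0)))
    else:
        xp = x.data
    acc = np.zeros((o, n, h, wd), dtype=np.float32)
    for i in range(k):
        xs = xp[:, :, i * dilation : i * dilation + h, :]
        acc += np.tensordot(w.data[:, :, i], xs, axes=([1], [1]))
    out_data = acc.transpose(1, 0, 2, 3) + b.data[None, :, None, None]
    out = Tensor(out_data, (x, w, b))

    def _backward() -> None:
        g = out.grad  # (N, O, H, W)
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(k):
            xs = xp[:, :, i * dilation : i * dilation + h, :]
            gw[:, :, i] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            gxp[:, :, i * dilation : i * dilation + h, :] += np.tensordot(
                w.data[:, :, i], g, axes=([0], [1])
            ).transpose(1, 0, 2, 3)
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(gxp[:, :, pad : pad + h, :] if pad else gxp)

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def _backward() -> None:
        x._accumulate(out.grad * (x.data > 0))

    out._backward = _backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even dims, got {h}x{w}")
    blocks = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = blocks.argmax(axis=-1)
    out = Tensor(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0], (x,))

    def _backward() -> None:
        gb = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], out.grad[..., None], axis=-1)
        gx = (
            gb.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    out._backward = _backward
    return out


def upsample2x2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling in both spatial axes."""
    n, c, h, w = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,))

    def _backward() -> None:
        g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accumulate(g)

    out._backward = _backward
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def _backward() -> None:
        a._accumulate(out.grad[:, :ca])
        b._accumulate(out.grad[:, ca:])

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires identical shapes")
    out = Tensor(a.data + b.data, (a, b))

    def _backward() -> None:
        a._accumulate(out.grad)
        b._accumulate(out.grad)

    out._backward = _backward
    return out


def softmax_depth(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the depth axis of (N, L, H, W)."""
    m = logits.max(axis=2, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=2, keepdims=True)


def softmax_depth_xent(logits: Tensor, target_depth: np.ndarray) -> Tensor:
    """Mean cross-entropy of the depth-axis softmax against integer targets.

    logits: (N, L, H, W); target_depth: (N, L, W) integer depth indices.
    """
    n, l, h, w = logits.data.shape
    if target_depth.shape != (n, l, w):
        raise ValueError(
            f"target shape {target_depth.shape} != expected {(n, l, w)}"
        )
    p = softmax_depth(logits.data.astype(np.float64))
    ni, li, wi = np.ix_(np.arange(n), np.arange(l), np.arange(w))
    picked = p[ni, li, target_depth, wi]
    count = n * l * w
    loss = -np.log(np.maximum(picked, 1e-30)).sum() / count
    out = Tensor(np.float32(loss), (logits,))

    def _backward() -> None:
        g = p.copy()
        g[ni, li, target_depth, wi] -= 1.0
        logits._accumulate((out.grad * g / count).astype(np.float32))

    out._backward = _backward
    return out


class AMSGrad:
    """AMSGrad: Adam with a non-decreasing second-moment estimate."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Sequence[float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._vhat = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v, vh in zip(self.params, self._m, self._v, self._vhat):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            np.maximum(vh, v, out=vh)
            mhat = m / bc1
            vhat = vh / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )
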