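"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the dual-stream segmentation
network on a CPU: tensors carry ``float32`` data and an optional closure
that maps the incoming gradient to gradients of the parents.  The tape
is implicit in the parent links; :func:`backward` topologically sorts
the graph reachable from one or more seed tensors and accumulates
gradients in ``float32``.

Feature maps have no batch axis — layouts are ``(C, D, H, W)`` — since
training proceeds one patch at a time (true stochastic gradient
descent).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Tensor", "backward", "conv3d", "conv_transpose3d", "maxpool2",
           "relu", "leaky_relu", "sigmoid", "add", "mul", "scale", "concat", "instance_norm"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad", "name")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.grad = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        tag = f" {self.name!r}" if self.name else ""
        return f"Tensor{tag}(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def backward(seeds: list[tuple[Tensor, np.ndarray]]) -> None:
    """Backpropagate from one or more output tensors.

    ``seeds`` pairs each output with dL/d(output).  Gradients accumulate
    into ``.grad`` of every tensor with ``requires_grad`` on the path.
    """
    order: list[Tensor] = []
    seen: set[int] = set()

    def topo(t: Tensor) -> None:
        stack = [(t, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

    grads: dict[int, np.ndarray] = {}
    for t, g in seeds:
        topo(t)
        g = np.asarray(g, dtype=np.float32)
        if g.shape != t.data.shape:
            raise ValueError(f"seed gradient shape {g.shape} != tensor shape {t.data.shape}")
        grads[id(t)] = grads.get(id(t), 0) + g

    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.grad_fn is None:
            node.grad = g if node.grad is None else node.grad + g
            continue
        parent_grads = node.grad_fn(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            grads[id(p)] = grads.get(id(p), 0) + pg


# ---------------------------------------------------------------------------
# operations

def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Plain 3D cross-correlation, stride 1. x: (C,D,H,W), w: (O,C,k,k,k)."""
    if pad:
        x = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    win = sliding_window_view(x, w.shape[2:], axis=(1, 2, 3))
    # win: (C, D', H', W', k, k, k)
    return np.tensordot(w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6])).astype(np.float32)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """'Same'-style 3D convolution (stride 1) with kernel k and padding pad."""
    y = _conv_raw(x.data, w.data, pad)
    if b is not None:
        y = y + b.data[:, None, None, None]
    k = w.data.shape[2]

    def grad_fn(gy: np.ndarray):
        xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        gw = np.tensordot(gy, win, axes=([1, 2, 3], [1, 2, 3])).astype(np.float32)
        # full correlation with channel-transposed, spatially flipped kernels
        wt = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        gx = _conv_raw(gy, wt, k - 1 - pad)
        gb = gy.sum(axis=(1, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(y, parents, grad_fn)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transpose convolution with 2x2x2 kernel, stride 2 (doubles resolution).

    Weight layout ``(C_in, C_out, 2, 2, 2)``.
    """
    y6 = np.einsum("idhw,ioabc->odahbwc", x.data, w.data, optimize=True)
    o, d, a, h, bb, wdim, c = y6.shape
    y = y6.reshape(o, d * 2, h * 2, wdim * 2).astype(np.float32)
    if b is not None:
        y = y + b.data[:, None, None, None]

    def grad_fn(gy: np.ndarray):
        g6 = gy.reshape(o, d, 2, h, 2, wdim, 2)
        gx = np.einsum("odahbwc,ioabc->idhw", g6, w.data, optimize=True).astype(np.float32)
        gw = np.einsum("idhw,odahbwc->ioabc", x.data, g6, optimize=True).astype(np.float32)
        gb = gy.sum(axis=(1, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(y, parents, grad_fn)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial dims must be even."""
    cdim, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    blocks = (x.data.reshape(cdim, d // 2, 2, h // 2, 2, w // 2, 2)
              .transpose(0, 1, 3, 5, 2, 4, 6)
              .reshape(cdim, d // 2, h // 2, w // 2, 8))
    idx = blocks.argmax(axis=-1)
    y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def grad_fn(gy: np.ndarray):
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, idx[..., None], gy[..., None], axis=-1)
        gx = (gblocks.reshape(cdim, d // 2, h // 2, w // 2, 2, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3, 6)
              .reshape(cdim, d, h, w))
        return (gx,)

    return Tensor(y, (x,), grad_fn)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    y = np.where(x.data > 0, x.data, slope * x.data)

    def grad_fn(gy: np.ndarray):
        return (gy * np.where(x.data > 0, np.float32(1.0), np.float32(slope)),)

    return Tensor(y, (x,), grad_fn)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def grad_fn(gy: np.ndarray):
        return (gy * (x.data > 0),)

    return Tensor(y, (x,), grad_fn)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)

    def grad_fn(gy: np.ndarray):
        return (gy * y * (1.0 - y),)

    return Tensor(y, (x,), grad_fn)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    return Tensor(a.data + b.data, (a, b), lambda gy: (gy, gy))


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"mul shape mismatch: {a.data.shape} vs {b.data.shape}")
    return Tensor(a.data * b.data, (a, b), lambda gy: (gy * b.data, gy * a.data))


def scale(x: Tensor, s: Tensor) -> Tensor:
    """Multiply a tensor by a scalar parameter (0-d tensor)."""
    if s.data.ndim != 0:
        raise ValueError("scale factor must be a 0-d tensor")
    y = x.data * s.data

    def grad_fn(gy: np.ndarray):
        return (gy * s.data, np.asarray((gy * x.data).sum(), dtype=np.float32))

    return Tensor(y, (x, s), grad_fn)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate feature maps along the channel axis."""
    y = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.data.shape[0] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(gy: np.ndarray):
        return tuple(np.split(gy, splits, axis=0))

    return Tensor(y, tuple(tensors), grad_fn)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes (no affine terms).

    With single-patch training this also serves as the batch-norm option
    at batch size one.
    """
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = ((x.data - mu) * inv).astype(np.float32)

    def grad_fn(gy: np.ndarray):
        m = gy.mean(axis=(1, 2, 3), keepdims=True)
        my = (gy * y).mean(axis=(1, 2, 3), keepdims=True)
        return ((inv * (gy - m - y * my)).astype(np.float32),)

    return Tensor(y, (x,), grad_fn)
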