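"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the reconstruction networks need are implemented:
2D convolution (stride 1, "same" padding, arbitrary dilation), batch
normalisation, ReLU/sigmoid, 2x2 max pooling, bilinear resizing, channel
concatenation, elementwise add and an MSE loss.  Convolutions are
evaluated as a loop over kernel taps, each tap a single BLAS matmul over
the batch, which is the fastest dense formulation available without a
compiled backend.

Every op builds a node in a dynamic graph; :meth:`Tensor.backward` runs a
topological sweep accumulating gradients into ``grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batchnorm2d",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "bilinear_resize",
    "resize_matrices",
    "concat",
    "add",
    "mse_loss",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-sweep from this (scalar or any-shape) tensor; seeds with
        ones of the output shape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph edges as we go
            node._backward = None
            node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution


def _window_view(xp: np.ndarray, kh: int, kw: int, d: int, h: int, w: int) -> np.ndarray:
    """Read-only dilated sliding-window view (N, C, kh, kw, H, W)."""
    n, c = xp.shape[:2]
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, h, w), (sn, sc, sh * d, sw * d, sh, sw), writeable=False
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """2D convolution, stride 1, zero "same" padding.

    ``x`` is (N, C, H, W), ``w`` is (O, C, k, k); output (N, O, H, W).
    Evaluated as one GEMM over an implicit im2col window view.
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    pad_h = dilation * (kh - 1) // 2
    pad_w = dilation * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_h, pad_h), (pad_w, pad_w)))
    view = _window_view(xp, kh, kw, dilation, h, wd)
    out = np.tensordot(w.data, view, axes=([1, 2, 3], [1, 2, 3])).transpose(1, 0, 2, 3)
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(gy: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w.accumulate(np.tensordot(gy, view, axes=([0, 2, 3], [0, 4, 5])))
        if x.requires_grad:
            t = np.tensordot(w.data, gy, axes=([0], [1]))  # (C, kh, kw, N, H, W)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd
                    ] += t[:, i, j].transpose(1, 0, 2, 3)
            if pad_h or pad_w:
                x.accumulate(gxp[:, :, pad_h : pad_h + h, pad_w : pad_w + wd])
            else:
                x.accumulate(gxp)

    return _node(np.ascontiguousarray(out), parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gy: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(gy.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        g_xhat = gy * gamma.data[None, :, None, None]
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            sum_g = g_xhat.sum(axis=(0, 2, 3))
            sum_gx = (g_xhat * xhat).sum(axis=(0, 2, 3))
            gx = (
                inv_std[None, :, None, None]
                / m
                * (m * g_xhat - sum_g[None, :, None, None] - xhat * sum_gx[None, :, None, None])
            )
        else:
            gx = g_xhat * inv_std[None, :, None, None]
        x.accumulate(gx.astype(x.data.dtype, copy=False))

    return _node(out.astype(x.data.dtype, copy=False), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pointwise and structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(gy * mask)

    return _node(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(gy * s * (1.0 - s))

    return _node(s, (x,), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5))

    def backward(gy: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gx = mask * (gy / counts)[:, :, :, None, :, None]
        x.accumulate(gx.reshape(n, c, h, w).astype(x.data.dtype, copy=False))

    return _node(out, (x,), backward)


def resize_matrices(
    in_hw: tuple[int, int], out_hw: tuple[int, int], dtype=np.float64
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column interpolation matrices for bilinear resizing with the
    half-pixel-centres (non-corner-aligned) convention."""

    def mat(n_in: int, n_out: int) -> np.ndarray:
        m = np.zeros((n_out, n_in), dtype=dtype)
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = src - i0
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i1] += frac
        return m

    return mat(in_hw[0], out_hw[0]), mat(in_hw[1], out_hw[1])


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N, C, H, W) to (N, C, *out_hw)."""
    h, w = x.shape[2], x.shape[3]
    wr, wc = resize_matrices((h, w), out_hw, dtype=x.data.dtype)
    out = wr @ x.data @ wc.T

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate((wr.T @ gy @ wc).astype(x.data.dtype, copy=False))

    return _node(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(gy: np.ndarray) -> None:
        for t, a, bnd in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * gy.ndim
                sl[axis] = slice(a, bnd)
                t.accumulate(gy[tuple(sl)])

    return _node(out, tuple(tensors), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch {a.shape} vs {b.shape}")
    out = a.data + b.data

    def backward(gy: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(gy)
        if b.requires_grad:
            b.accumulate(gy)

    return _node(out, (a, b), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=pred.data.dtype)
    if target.shape != pred.shape:
        raise ValueError("loss shape mismatch")
    diff = pred.data - target
    out = np.asarray(np.mean(diff**2), dtype=pred.data.dtype)

    def backward(gy: np.ndarray) -> None:
        if pred.requires_grad:
            pred.accumulate((2.0 / diff.size) * diff * gy)

    return _node(out, (pred,), backward)
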