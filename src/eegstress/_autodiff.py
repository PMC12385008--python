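"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations that produced
it; ``backward()`` on a scalar loss topologically replays the tape and
accumulates gradients into every tensor created with ``requires_grad=True``.
Only the operations the stress classifier needs are implemented: elementwise
arithmetic with broadcasting, matmul, activations, reductions, concat/
reshape/narrow, 1-D convolution, max-pooling and a fused softmax
cross-entropy loss.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "softmax_cross_entropy"]


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = tuple(prev)
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming buffer may be shared with another edge
            self.grad = np.array(grad, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = back
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = back
        return out

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / np.sqrt(self.data))

        out._backward = back
        return out

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = back
        return out

    def sigmoid(self):
        s = expit(self.data)
        out = Tensor(s, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = back
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t**2))

        out._backward = back
        return out

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = back
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        index = [slice(None)] * self.data.ndim
        index[axis] = slice(start, start + length)
        index = tuple(index)
        out = Tensor(self.data[index], (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = g
                self._accumulate(full)

        out._backward = back
        return out

    # -- autodiff driver ----------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out._backward = back
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation), stride 1.

    ``x``: (B, Cin, L), ``w``: (Cout, Cin, K), ``b``: (Cout,) ->
    (B, Cout, L + 2*padding - K + 1).
    """
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    batch, c_in, l_pad = xp.shape
    c_out, _, k = w.data.shape
    l_out = l_pad - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    # im2col so the contraction is one BLAS gemm
    col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
        batch * l_out, c_in * k
    )
    wmat = w.data.reshape(c_out, c_in * k)
    out_data = (col @ wmat.T).reshape(batch, l_out, c_out).transpose(0, 2, 1)
    out_data += b.data[None, :, None]
    out = Tensor(out_data, (x, w, b))

    def back(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(batch * l_out, c_out)
        if w.requires_grad:
            w._accumulate((gmat.T @ col).reshape(c_out, c_in, k))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcol = (gmat @ wmat).reshape(batch, l_out, c_in, k)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, :, kk : kk + l_out] += gcol[:, :, :, kk].transpose(0, 2, 1)
            x._accumulate(gxp[:, :, padding : l_pad - padding] if padding else gxp)

    out._backward = back
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (floor division).

    Ties within a window route the gradient to the earlier sample.
    """
    b, c, l = x.data.shape
    l_out = l // size
    view = x.data[:, :, : l_out * size].reshape(b, c, l_out, size)
    if size == 2:
        right = view[..., 1] > view[..., 0]
        out_data = np.where(right, view[..., 1], view[..., 0])
        idx = right.astype(np.intp)
    else:
        idx = view.argmax(axis=3)
        out_data = np.take_along_axis(view, idx[..., None], axis=3)[..., 0]
    out = Tensor(out_data, (x,))

    def back(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        if l == l_out * size:
            gview = gx.reshape(b, c, l_out, size)  # view
        else:
            gview = np.zeros((b, c, l_out, size))
        if size == 2:
            np.copyto(gview[..., 0], g, where=idx == 0)
            np.copyto(gview[..., 1], g, where=idx == 1)
        else:
            np.put_along_axis(gview, idx[..., None], g[..., None], axis=3)
        if l != l_out * size:
            gx[:, :, : l_out * size] = gview.reshape(b, c, l_out * size)
        x._accumulate(gx)

    out._backward = back
    return out


def batch_norm(
    x: Tensor,
    scale: Tensor,
    offset: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    batch_stats: bool,
) -> Tensor:
    """Fused per-channel normalization of a (B, C, L) tensor.

    ``mean``/``var`` are (1, C, 1) statistics. With ``batch_stats`` they are
    treated as functions of ``x`` (training-mode backward); otherwise as
    constants (inference-mode backward).
    """
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = Tensor(scale.data * xhat + offset.data, (x, scale, offset))

    def back(g):
        if scale.requires_grad:
            scale._accumulate((g * xhat).sum(axis=(0, 2), keepdims=True))
        if offset.requires_grad:
            offset._accumulate(g.sum(axis=(0, 2), keepdims=True))
        if not x.requires_grad:
            return
        ghat = g * scale.data
        if not batch_stats:
            x._accumulate(ghat * inv_std)
            return
        m = x.data.shape[0] * x.data.shape[2]
        sum_ghat = ghat.sum(axis=(0, 2), keepdims=True)
        sum_ghat_xhat = (ghat * xhat).sum(axis=(0, 2), keepdims=True)
        x._accumulate(inv_std * (ghat - sum_ghat / m - xhat * sum_ghat_xhat / m))

    out._backward = back
    return out


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of integer targets; returns (loss, probabilities)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss_val = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
    out = Tensor(loss_val, (logits,))

    def back(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), y] -= 1.0
            logits._accumulate(g * grad / n)

    out._backward = back
    return out, probs
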