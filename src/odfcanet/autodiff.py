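"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the network needs: broadcast
arithmetic, matrix products (including batched), elementwise nonlinearities,
axis reductions, shape manipulation, concatenation/slicing, 2-D convolution
(shared kernel and per-sample kernel variants) and max pooling. Everything is
stored in float64; convolution is implemented by im2col with strided window
views so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv2d_per_sample",
    "maxpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(grad):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda grad: (-grad,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def backward(grad):
            return (grad * exponent * self.data ** (exponent - 1),)

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(grad):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = grad @ np.swapaxes(b, -1, -2) if b.ndim > 1 else grad * b
            else:
                gb_t = np.swapaxes(b, -1, -2) if b.ndim > 1 else b[None, :]
                ga = grad @ gb_t if b.ndim > 1 else np.multiply.outer(grad, b)
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ grad if a.ndim > 1 else a * grad
            else:
                ga_t = np.swapaxes(a, -1, -2) if a.ndim > 1 else a[:, None]
                gb = ga_t @ grad if a.ndim > 1 else ga_t * grad
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # ---------------------------------------------------------- element-wise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda grad: (grad * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda grad: (grad / self.data,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda grad: (grad * s * (1.0 - s),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda grad: (grad * mask,)
        return out

    def sqrt(self):
        return self ** 0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda grad: (grad.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda grad: (grad.transpose(inv),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, key, grad)
            return (g,)

        out._backward = backward
        return out

    # --------------------------------------------------------------- engine
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if isinstance(p, Tensor) and p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not isinstance(parent, Tensor) or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# ---------------------------------------------------------------- free ops
def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    out._backward = backward
    return out


def _im2col(xd: np.ndarray, k: int, stride: int, padding: int):
    """Return (cols: N x L x C*k*k, h_out, w_out) for an N,C,H,W array."""
    h_out = (xd.shape[2] + 2 * padding - k) // stride + 1
    w_out = (xd.shape[3] + 2 * padding - k) // stride + 1
    if h_out < 1 or w_out < 1:
        raise ValueError(
            f"non-positive output spatial size ({h_out}x{w_out}) for input "
            f"{xd.shape[2]}x{xd.shape[3]}, kernel {k}, stride {stride}, padding {padding}"
        )
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, h_out, w_out = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h_out * w_out, c * k * k)
    return np.ascontiguousarray(cols), h_out, w_out


def _col2im(grad_cols, n, c, h, w, k, stride, padding, h_out, w_out):
    hp, wp = h + 2 * padding, w + 2 * padding
    gx = np.zeros((n, c, hp, wp))
    gc = grad_cols.reshape(n, h_out, w_out, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for u in range(k):
        for v in range(k):
            gx[:, :, u : u + stride * h_out : stride, v : v + stride * w_out : stride] += gc[
                :, :, :, :, u, v
            ]
    if padding:
        gx = gx[:, :, padding : padding + h, padding : padding + w]
    return gx


def conv2d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of x (N,C,H,W) with a shared kernel (c_out,C,k,k)."""
    n, c, h, w = x.shape
    c_out, c_in, k, k2 = weight.shape
    if k != k2:
        raise ValueError("only square kernels are supported")
    if c_in != c:
        raise ValueError(f"input has {c} channels but kernel expects {c_in}")
    cols, h_out, w_out = _im2col(x.data, k, stride, padding)
    if h_out < 1 or w_out < 1:
        raise ValueError(f"non-positive output spatial size ({h_out}x{w_out})")
    wd = weight.data.reshape(c_out, -1)
    out_d = cols @ wd.T  # N, L, c_out
    out = Tensor(
        out_d.transpose(0, 2, 1).reshape(n, c_out, h_out, w_out),
        x.requires_grad or weight.requires_grad,
        (x, weight),
    )

    def backward(grad):
        g = grad.reshape(n, c_out, h_out * w_out).transpose(0, 2, 1)  # N, L, c_out
        g2 = np.ascontiguousarray(g).reshape(n * h_out * w_out, c_out)
        grad_w = (g2.T @ cols.reshape(n * h_out * w_out, -1)).reshape(weight.shape)
        grad_cols = g @ wd  # N, L, C*k*k
        grad_x = _col2im(grad_cols, n, c, h, w, k, stride, padding, h_out, w_out)
        return (grad_x, grad_w)

    out._backward = backward
    return out


def conv2d_per_sample(x: Tensor, weights: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation where each sample carries its own kernel.

    x: (N,C,H,W); weights: (N,c_out,C,k,k) — the dynamic-convolution case.
    """
    n, c, h, w = x.shape
    n2, c_out, c_in, k, _ = weights.shape
    if n2 != n:
        raise ValueError(f"batch mismatch: {n} inputs vs {n2} kernels")
    if c_in != c:
        raise ValueError(f"input has {c} channels but kernel expects {c_in}")
    cols, h_out, w_out = _im2col(x.data, k, stride, padding)
    if h_out < 1 or w_out < 1:
        raise ValueError(f"non-positive output spatial size ({h_out}x{w_out})")
    wd = weights.data.reshape(n, c_out, -1)
    out_d = np.matmul(cols, wd.transpose(0, 2, 1))  # N, L, c_out
    out = Tensor(
        out_d.transpose(0, 2, 1).reshape(n, c_out, h_out, w_out),
        x.requires_grad or weights.requires_grad,
        (x, weights),
    )

    def backward(grad):
        g = grad.reshape(n, c_out, h_out * w_out)  # N, c_out, L
        grad_w = np.matmul(g, cols).reshape(weights.shape)
        grad_cols = np.matmul(g.transpose(0, 2, 1), wd)
        grad_x = _col2im(grad_cols, n, c, h, w, k, stride, padding, h_out, w_out)
        return (grad_x, grad_w)

    out._backward = backward
    return out


def weighted_kernel_mix(kernels: Tensor, a_s: Tensor, a_c: Tensor, a_f: Tensor,
                        a_w: Tensor) -> Tensor:
    """Attention-modulated sum of a kernel bank, one kernel per sample.

    kernels: (n, c_out, c_in, k, k); a_s: (N, k, k); a_c: (N, c_in);
    a_f: (N, c_out); a_w: (N, n). Returns (N, c_out, c_in, k, k) equal to
    sum_i a_w[:, i] * kernels[i] * a_s * a_c * a_f with standard
    broadcasting, fused into one einsum for speed.
    """
    args = (kernels, a_s, a_c, a_f, a_w)
    kd, sd, cd, fd, wd = (t.data for t in args)
    n_bank, c_out, c_in, k, _ = kd.shape
    n = wd.shape[0]
    kflat = kd.reshape(n_bank, -1)
    mixed = (wd @ kflat).reshape(n, c_out, c_in, k, k)  # sum_i a_w[:, i] W_i
    modulation = (fd[:, :, None, None, None]
                  * cd[:, None, :, None, None]
                  * sd[:, None, None, :, :])
    out = Tensor(mixed * modulation, any(t.requires_grad for t in args), args)

    def backward(grad):
        g_mixed = grad * modulation
        g_mod = grad * mixed
        g_mixed_flat = g_mixed.reshape(n, -1)
        grad_k = (wd.T @ g_mixed_flat).reshape(kd.shape)
        grad_w = g_mixed_flat @ kflat.T
        oc = (g_mod * sd[:, None, None, :, :]).sum(axis=(3, 4))  # N, c_out, c_in
        grad_f = (oc * cd[:, None, :]).sum(axis=2)
        grad_c = (oc * fd[:, :, None]).sum(axis=1)
        ckk = (g_mod * fd[:, :, None, None, None]).sum(axis=1)   # N, c_in, k, k
        grad_s = (ckk * cd[:, :, None, None]).sum(axis=1)
        return (grad_k, grad_s, grad_c, grad_f, grad_w)

    out._backward = backward
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = sliding_window_view(xd, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    n_, c_, h_out, w_out = win.shape[:4]
    flat = win.reshape(n, c, h_out, w_out, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def backward(grad):
        hp, wp = h + 2 * padding, w + 2 * padding
        gx = np.zeros((n, c, hp, wp))
        ku, kv = np.divmod(arg, kernel)
        ni, ci, oi, oj = np.indices(arg.shape)
        rows = oi * stride + ku
        colz = oj * stride + kv
        np.add.at(gx, (ni, ci, rows, colz), grad)
        if padding:
            gx = gx[:, :, padding : padding + h, padding : padding + w]
        return (gx,)

    out._backward = backward
    return out
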