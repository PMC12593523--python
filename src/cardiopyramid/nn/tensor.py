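"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This module provides the minimum surface needed by the pyramid network,
attention module and encoder–decoder classifier: broadcast arithmetic,
matmul, reductions, shape ops, elementwise nonlinearities, 3-D convolution
(with stride and zero padding), zero-insertion upsampling (for transposed
convolution) and 3-D max pooling.  Gradients are accumulated by topological
back-propagation over the recorded tape.

Floating dtype is preserved: float64 inputs stay float64 (used by the
numerically strict attention contracts), everything else is promoted to
float32 (the training path).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "maximum"]


def _as_array(data) -> np.ndarray:
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = _GradMode.enabled and (
            requires_grad or any(p.requires_grad for p in parents)
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic protocol ---------------------------------------------------- #

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _set_backward(self, fn) -> None:
        if self.requires_grad:
            self._backward = fn

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this (typically scalar) tensor.

        The graph is torn down as it is consumed: each intermediate node's
        gradient, closure and parent links are released right after its
        backward step, keeping peak memory close to a single graph traversal.
        Leaf tensors (parameters) keep their accumulated ``grad``.
        """
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
                stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # intermediate node: release tape state
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------- #

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._set_backward(bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._set_backward(lambda g: self._accumulate(-g))
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._set_backward(bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        out._set_backward(bw)
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._set_backward(
            lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1))
        )
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._set_backward(bw)
        return out

    __matmul__ = matmul

    # -- reductions -------------------------------------------------------- #

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(self.data.dtype))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(self.data.dtype))

        out._set_backward(bw)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops --------------------------------------------------------- #

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g.reshape(self.shape)))
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g.transpose(inv)))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(self.data.swapaxes(a, b), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g.swapaxes(a, b)))
        return out

    def flip(self, axes) -> "Tensor":
        out = Tensor(np.flip(self.data, axes), parents=(self,))
        out._set_backward(lambda g: self._accumulate(np.flip(g, axes)))
        return out

    def expand_dims(self, axis: int) -> "Tensor":
        out = Tensor(np.expand_dims(self.data, axis), parents=(self,))
        out._set_backward(lambda g: self._accumulate(np.squeeze(g, axis)))
        return out

    # -- elementwise nonlinearities ---------------------------------------- #

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g * out.data))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g / self.data))
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g * (1.0 - out.data**2)))
        return out

    def softplus(self) -> "Tensor":
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))
        out._set_backward(
            lambda g: self._accumulate(g / (1.0 + np.exp(-self.data)))
        )
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._set_backward(lambda g: self._accumulate(g * (self.data > 0)))
        return out

    def mish(self) -> "Tensor":
        """x * tanh(softplus(x)) — smooth non-monotonic activation.

        Fused forward/backward: d/dx = t + x * (1 - t^2) * sigmoid(x) with
        t = tanh(softplus(x)).
        """
        t = np.tanh(np.logaddexp(0.0, self.data))
        out = Tensor(self.data * t, parents=(self,))

        def bw(g):
            sig = 1.0 / (1.0 + np.exp(-self.data))
            self._accumulate(g * (t + self.data * (1.0 - t * t) * sig))

        out._set_backward(bw)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def batchnorm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        eps: float = 1e-4,
    ) -> tuple["Tensor", np.ndarray, np.ndarray]:
        """Fused per-channel batch normalization over axes (0, 2, 3, 4).

        ``self`` is (N, C, D1, D2, D3); gamma/beta are length-C.  Returns
        ``(out, batch_mean, batch_var)`` with the standard analytic gradient.
        """
        x = self.data
        axes = (0, 2, 3, 4)
        m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        gr = gamma.data.reshape(1, -1, 1, 1, 1)
        out = Tensor(
            (xhat * gr + beta.data.reshape(1, -1, 1, 1, 1)).astype(x.dtype),
            parents=(self, gamma, beta),
        )

        def bw(g):
            gsum = g.sum(axis=axes, keepdims=True)
            gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
            if beta.requires_grad:
                beta._accumulate(gsum.ravel())
            if gamma.requires_grad:
                gamma._accumulate(gx_sum.ravel())
            if self.requires_grad:
                self._accumulate(
                    (gr * inv) * (g - gsum / m - xhat * (gx_sum / m))
                )

        out._set_backward(bw)
        return out, mu.ravel(), var.ravel()

    # -- softmax ----------------------------------------------------------- #

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax; the max shift is treated as constant
        (exact, since softmax is shift-invariant)."""
        shifted = self - Tensor(np.max(self.data, axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- convolution machinery --------------------------------------------- #

    def conv3d(self, weight: "Tensor", stride=(1, 1, 1), pad=(0, 0, 0)) -> "Tensor":
        """3-D cross-correlation.

        ``self``: (N, C, D1, D2, D3); ``weight``: (O, C, k1, k2, k3).
        Output: (N, O, M1, M2, M3) with
        ``M_i = floor((D_i + 2*pad_i - k_i)/stride_i) + 1``.
        """
        weight = Tensor._lift(weight)
        x, w = self.data, weight.data
        s, p = tuple(stride), tuple(pad)
        k = w.shape[2:]
        if x.ndim != 5 or w.ndim != 5 or x.shape[1] != w.shape[1]:
            raise ValueError(f"conv3d shape mismatch: x{x.shape} w{w.shape}")
        for i in range(3):
            if k[i] > x.shape[2 + i] + 2 * p[i]:
                raise ValueError(
                    f"kernel {k[i]} exceeds padded input on axis {i}"
                )
        xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
        M = tuple((xp.shape[2 + i] - k[i]) // s[i] + 1 for i in range(3))
        N, C = x.shape[:2]
        O = w.shape[0]
        offsets = [
            (a, b, c) for a in range(k[0]) for b in range(k[1]) for c in range(k[2])
        ]
        nk = len(offsets)
        Mp = M[0] * M[1] * M[2]

        def _slc(d: tuple[int, int, int]):
            return (
                slice(None),
                slice(None),
                slice(d[0], d[0] + s[0] * M[0], s[0]),
                slice(d[1], d[1] + s[1] * M[1], s[1]),
                slice(d[2], d[2] + s[2] * M[2], s[2]),
            )

        # im2col laid out (nk, C, N, M1, M2, M3): every per-offset copy moves
        # contiguous runs along the innermost spatial axis, and the whole
        # contraction is a single GEMM (BLAS consumes the transpose without a
        # copy).  The column matrix is cached on the tape for backward.
        xcol = np.empty((nk, C, N, *M), dtype=xp.dtype)
        for di, d in enumerate(offsets):
            xcol[di] = xp[_slc(d)].swapaxes(0, 1)
        xmat = xcol.reshape(nk * C, N * Mp)
        wmat = (
            w.reshape(O, C, nk).transpose(2, 1, 0).reshape(nk * C, O).astype(xp.dtype)
        )
        out_data = (xmat.T @ wmat).reshape(N, *M, O)
        out = Tensor(
            np.ascontiguousarray(np.moveaxis(out_data, -1, 1)), parents=(self, weight)
        )

        def bw(g):
            gm = np.moveaxis(g, 1, -1).reshape(N * Mp, O)
            if weight.requires_grad:
                gw = (xmat @ gm).reshape(nk, C, O).transpose(2, 1, 0).reshape(w.shape)
                weight._accumulate(gw.astype(w.dtype))
            if self.requires_grad:
                gcol = (wmat @ gm.T).reshape(nk, C, N, *M)
                gxp = np.zeros_like(xp)
                for di, d in enumerate(offsets):
                    gxp[_slc(d)] += gcol[di].swapaxes(0, 1)
                gx = gxp[
                    :,
                    :,
                    p[0] : p[0] + x.shape[2],
                    p[1] : p[1] + x.shape[3],
                    p[2] : p[2] + x.shape[4],
                ]
                self._accumulate(gx)

        out._set_backward(bw)
        return out

    def zero_insert(self, stride=(1, 1, 1)) -> "Tensor":
        """Insert ``stride-1`` zeros between samples along the spatial axes
        (the upsampling half of a transposed convolution)."""
        s = tuple(stride)
        x = self.data
        f = tuple((x.shape[2 + i] - 1) * s[i] + 1 for i in range(3))
        z = np.zeros((x.shape[0], x.shape[1], *f), dtype=x.dtype)
        z[:, :, :: s[0], :: s[1], :: s[2]] = x
        out = Tensor(z, parents=(self,))
        out._set_backward(
            lambda g: self._accumulate(g[:, :, :: s[0], :: s[1], :: s[2]])
        )
        return out

    def maxpool3d(self, pool=(2, 2, 2)) -> "Tensor":
        """Non-overlapping 3-D max pooling; trailing remainders are dropped.

        Axes whose size is smaller than the pool size are left unpooled.
        """
        q = tuple(
            pool[i] if self.data.shape[2 + i] >= pool[i] else 1 for i in range(3)
        )
        x = self.data
        N, C = x.shape[:2]
        M = tuple(x.shape[2 + i] // q[i] for i in range(3))
        xc = x[:, :, : M[0] * q[0], : M[1] * q[1], : M[2] * q[2]]
        xr = xc.reshape(N, C, M[0], q[0], M[1], q[1], M[2], q[2])
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, *M, -1)
        arg = np.argmax(xr, axis=-1)
        out = Tensor(np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0], parents=(self,))

        def bw(g):
            gr = np.zeros((N, C, *M, q[0] * q[1] * q[2]), dtype=g.dtype)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gr = gr.reshape(N, C, M[0], M[1], M[2], q[0], q[1], q[2])
            gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(
                N, C, M[0] * q[0], M[1] * q[1], M[2] * q[2]
            )
            gx = np.zeros_like(x)
            gx[:, :, : M[0] * q[0], : M[1] * q[1], : M[2] * q[2]] = gr
            self._accumulate(gx)

        out._set_backward(bw)
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(a), int(b))
                t._accumulate(g[tuple(idx)])

    out._set_backward(bw)
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; the subgradient follows the winning branch
    (ties go to the first argument)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.shape))

    out._set_backward(bw)
    return out
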