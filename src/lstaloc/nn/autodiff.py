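"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the localization network needs: broadcasted
arithmetic, batched matrix products, the usual pointwise nonlinearities,
softmax, reductions, shape manipulation, fancy-index gather/scatter and an
adaptive max-pool. Gradients accumulate into ``Tensor.grad`` on ``backward()``.

Every tensor stores float32 data unless constructed otherwise; parameters are
float32 throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "adaptive_max_pool",
    "ragged_adaptive_max_pool",
    "unfold",
    "conv1d_valid",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
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
        if isinstance(data, (np.ndarray, np.generic)):
            self.data = np.asarray(data)  # keep dtype (float32 in normal use)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- graph machinery ------------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        order: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape)))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return (
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            )

        return self._make(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return self._make(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            return ((self, g * (self.data > 0)),)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - out_data**2)),)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return ((self, g / self.data),)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            return ((self, g * ((self.data >= lo) & (self.data <= hi))),)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((self, out_data * (g - dot)),)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(gg, self.shape).copy()),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[a] for a in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            return ((self, g.reshape(orig)),)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)

        return self._make(out_data, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.shape, dtype=np.float32) >= p).astype(self.data.dtype) / (1.0 - p)

        def backward(g):
            return ((self, g * mask),)

        return self._make(self.data * mask, (self,), backward)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            grads.append((t, g[tuple(sl)]))
        return grads

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        slices = np.moveaxis(g, axis, 0)
        return [(t, slices[i]) for i, t in enumerate(tensors)]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# -- pooling / unfolding ------------------------------------------------------

_BIN_CACHE: dict[tuple[int, int], tuple[np.ndarray, int]] = {}


def pool_bins(length: int, target: int) -> np.ndarray:
    """Index matrix (target, m) of the adaptive max-pool bins.

    Bin ``i`` covers input positions ``floor(i*length/target)`` through
    ``ceil((i+1)*length/target) - 1``; rows are padded by repeating the last
    in-bin index so a plain gather + max realizes the pool. Works for
    ``length < target`` (bins then repeat elements).
    """
    key = (length, target)
    cached = _BIN_CACHE.get(key)
    if cached is not None:
        return cached[0]
    i = np.arange(target)
    starts = (i * length) // target
    ends = -((-(i + 1) * length) // target)  # ceil division
    m = int((ends - starts).max())
    idx = starts[:, None] + np.arange(m)[None, :]
    idx = np.minimum(idx, (ends - 1)[:, None])
    if len(_BIN_CACHE) < 4096:
        _BIN_CACHE[key] = (idx, m)
    return idx


def adaptive_max_pool(x: Tensor, target: int, axis: int = -2) -> Tensor:
    """Adaptive max-pool along ``axis`` to exactly ``target`` positions.

    ``x`` is (..., positions, channels) with the default ``axis=-2``. The
    forward pass gathers channels-first so the per-bin max runs over a
    contiguous last axis; the bin argmax needed for the gradient is only
    computed when backward actually runs.
    """
    if target < 1:
        raise ValueError("pool target must be >= 1")
    axis = axis % x.ndim
    if axis != x.ndim - 2:
        raise ValueError("pooling axis must be the second-to-last (positions)")
    length = x.shape[axis]
    idx = pool_bins(length, target)  # (target, m)
    xt = np.ascontiguousarray(np.swapaxes(x.data, -1, -2))  # (..., C, L)
    gathered = xt[..., idx]  # (..., C, target, m)
    out_data = np.swapaxes(gathered.max(axis=-1), -1, -2)  # (..., target, C)

    def backward(g):
        am = gathered.argmax(axis=-1)  # (..., C, target)
        orig = idx[np.arange(target), am]  # input positions, (..., C, target)
        gt = np.swapaxes(g, -1, -2)  # (..., C, target)
        # positions repeat across bins when length < target: accumulate via bincount
        lead = int(np.prod(x.shape[:-2], dtype=np.int64)) * x.shape[-1]
        offsets = np.arange(lead, dtype=np.int64).reshape(orig.shape[:-1]) * length
        lin = (orig + offsets[..., None]).ravel()
        flat = np.bincount(lin, weights=gt.ravel(), minlength=lead * length)
        gx = np.swapaxes(flat.reshape(orig.shape[:-1] + (length,)), -1, -2)
        return ((x, np.ascontiguousarray(gx, dtype=x.data.dtype)),)

    return x._make(np.ascontiguousarray(out_data), (x,), backward)


def ragged_adaptive_max_pool(x: Tensor, lengths, target: int) -> Tensor:
    """Adaptive max-pool of a length-padded batch.

    ``x`` is (B, Lmax, C); sample ``b`` occupies positions ``0..lengths[b]-1``
    and is pooled with the same bin rule as :func:`adaptive_max_pool` over its
    own length, ignoring the padding. Output is (B, target, C).
    """
    if target < 1:
        raise ValueError("pool target must be >= 1")
    lengths = np.asarray(lengths)
    B, Lmax, C = x.shape
    if lengths.shape[0] != B or lengths.max() > Lmax or lengths.min() < 1:
        raise ValueError("invalid lengths for padded batch")
    bins = [pool_bins(int(n), target) for n in lengths]
    m = max(b.shape[1] for b in bins)
    idx = np.stack(
        [np.pad(b, ((0, 0), (0, m - b.shape[1])), mode="edge") for b in bins]
    )  # (B, target, m)
    xt = np.ascontiguousarray(np.swapaxes(x.data, -1, -2))  # (B, C, Lmax)
    flat_idx = idx.reshape(B, 1, target * m)
    gathered = np.take_along_axis(xt, np.broadcast_to(flat_idx, (B, C, target * m)), axis=-1)
    gathered = gathered.reshape(B, C, target, m)
    out_data = np.ascontiguousarray(np.swapaxes(gathered.max(axis=-1), -1, -2))

    def backward(g):
        am = gathered.argmax(axis=-1)  # (B, C, target)
        orig = np.take_along_axis(idx[:, None, :, :], am[..., None], axis=-1)[..., 0]
        gt = np.swapaxes(g, -1, -2)  # (B, C, target)
        offsets = np.arange(B * C, dtype=np.int64).reshape(B, C) * Lmax
        lin = (orig + offsets[..., None]).ravel()
        flat = np.bincount(lin, weights=gt.ravel(), minlength=B * C * Lmax)
        gx = np.swapaxes(flat.reshape(B, C, Lmax), -1, -2)
        return ((x, np.ascontiguousarray(gx, dtype=x.data.dtype)),)

    return x._make(out_data, (x,), backward)


def unfold(x: Tensor, kernel: int) -> Tensor:
    """Sliding windows for valid 1D convolution.

    (..., L, C) -> (..., L - kernel + 1, kernel * C); window j holds positions
    j .. j+kernel-1 concatenated along channels.
    """
    L = x.shape[-2]
    C = x.shape[-1]
    if L < kernel:
        raise ValueError(f"sequence of {L} positions shorter than kernel {kernel}")
    Lout = L - kernel + 1
    out_data = np.concatenate([x.data[..., j : j + Lout, :] for j in range(kernel)], axis=-1)

    def backward(g):
        gx = np.zeros_like(x.data)
        for j in range(kernel):
            gx[..., j : j + Lout, :] += g[..., :, j * C : (j + 1) * C]
        return ((x, gx),)

    return x._make(out_data, (x,), backward)


def conv1d_valid(x: Tensor, weight: Tensor, bias: Tensor, kernel: int) -> Tensor:
    """Fused valid 1D convolution: (..., L, C) x (kernel*C, F) -> (..., L-k+1, F).

    Equivalent to ``unfold(x, kernel) @ weight + bias`` but computed as a sum
    of shifted matmuls, avoiding the unfolded copy in both passes.
    """
    L, C = x.shape[-2], x.shape[-1]
    if L < kernel:
        raise ValueError(f"sequence of {L} positions shorter than kernel {kernel}")
    Lout = L - kernel + 1
    W = weight.data.reshape(kernel, C, -1)
    out_data = np.ascontiguousarray(x.data[..., 0:Lout, :]) @ W[0]
    for j in range(1, kernel):
        out_data += x.data[..., j : j + Lout, :] @ W[j]
    out_data += bias.data

    def backward(g):
        gflat = g.reshape(-1, g.shape[-1])
        gW = np.empty_like(W)
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for j in range(kernel):
            xs = x.data[..., j : j + Lout, :].reshape(-1, C)
            gW[j] = xs.T @ gflat
            if gx is not None:
                gx[..., j : j + Lout, :] += g @ W[j].T
        gb = gflat.sum(axis=0)
        out = [(weight, gW.reshape(weight.shape)), (bias, gb)]
        if gx is not None:
            out.append((x, gx))
        return out

    return x._make(out_data, (x, weight, bias), backward)
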