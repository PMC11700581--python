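"""Neural-network building blocks on top of the autodiff core.

The conventions mirror the common deep-learning toolkits: a ``Module`` tree
with ``parameters()`` / ``train()`` / ``eval()`` / ``state_dict()``, linear and
valid 1D convolution layers, layer normalization, and a fused LSTM whose
backward pass is hand-derived backpropagation through time (verified against a
per-step oracle in the test suite).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d_valid

try:  # optional JIT for the recurrence loops; numpy path is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


__all__ = ["Module", "Linear", "Conv1d", "LayerNorm", "LSTM", "uniform_init"]


@njit(cache=True)
def _lstm_forward_kernel(xw, U, gates, cells, tanhc, hprev, hs):
    G, B, T, H4 = xw.shape
    H = H4 // 4
    h = np.zeros((G, B, H), dtype=xw.dtype)
    c = np.zeros((G, B, H), dtype=xw.dtype)
    for t in range(T):
        for g in range(G):
            hprev[t, g] = h[g]
            z = xw[g, :, t, :] + np.dot(h[g], U[g])
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            cand = np.tanh(z[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
            c[g] = f * c[g] + i * cand
            tc = np.tanh(c[g])
            h[g] = o * tc
            gates[t, g, :, :H] = i
            gates[t, g, :, H : 2 * H] = f
            gates[t, g, :, 2 * H : 3 * H] = cand
            gates[t, g, :, 3 * H :] = o
            cells[t, g] = c[g]
            tanhc[t, g] = tc
            hs[g, :, t, :] = h[g]


@njit(cache=True)
def _lstm_backward_kernel(gout, data, W, U, gates, cells, tanhc, hprev, dW, dU, db, dx):
    G, B, T, _ = data.shape
    H = U.shape[1]
    dh = np.zeros((G, B, H), dtype=data.dtype)
    dc = np.zeros((G, B, H), dtype=data.dtype)
    dz = np.empty((B, 4 * H), dtype=data.dtype)
    for t in range(T - 1, -1, -1):
        for g in range(G):
            i = gates[t, g, :, :H]
            f = gates[t, g, :, H : 2 * H]
            cand = gates[t, g, :, 2 * H : 3 * H]
            o = gates[t, g, :, 3 * H :]
            tc = tanhc[t, g]
            if t > 0:
                cprev = cells[t - 1, g]
            else:
                cprev = np.zeros((B, H), dtype=data.dtype)
            dht = dh[g] + gout[g, :, t, :]
            do = dht * tc
            dcg = dc[g] + dht * o * (1.0 - tc * tc)
            dz[:, :H] = dcg * cand * i * (1.0 - i)
            dz[:, H : 2 * H] = dcg * cprev * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dcg * i * (1.0 - cand * cand)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dW[g] += np.dot(data[g, :, t, :].T.copy(), dz)
            dU[g] += np.dot(hprev[t, g].T.copy(), dz)
            db[g, 0] += dz.sum(axis=0)
            dx[g, :, t, :] = np.dot(dz, W[g].T.copy())
            dh[g] = np.dot(dz, U[g].T.copy())
            dc[g] = dcg * f


def uniform_init(rng: np.random.Generator, shape, bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32), requires_grad=True)


class Module:
    """Base class: submodules and parameters discovered from attributes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{full}.{i}", item))
        return out

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, value in state.items():
            if params[name].data.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name].data = np.asarray(value, dtype=np.float32).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = uniform_init(rng, (in_features, out_features), bound)
        self.bias = uniform_init(rng, (out_features,), bound)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Valid (no-padding) 1D convolution over (..., positions, channels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        # He-uniform gain: every convolution here feeds a rectifier, and the
        # stacked stages attenuate signal badly under smaller-scale inits
        bound = np.sqrt(6.0 / (in_channels * kernel))
        self.weight = uniform_init(rng, (kernel * in_channels, out_channels), bound)
        self.bias = uniform_init(rng, (out_channels,), 1.0 / np.sqrt(in_channels * kernel))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_valid(x, self.weight, self.bias, self.kernel)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(width, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(width, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        data = x.data
        mu = data.mean(axis=-1, keepdims=True)
        var = data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (data - mu) * inv
        gamma, beta = self.gamma, self.beta

        def backward(g):
            n = data.shape[-1]
            gy = g * gamma.data
            gxhat_mean = gy.mean(axis=-1, keepdims=True)
            gxhat_dot = (gy * xhat).mean(axis=-1, keepdims=True)
            gx = inv * (gy - gxhat_mean - xhat * gxhat_dot)
            ggamma = (g * xhat).reshape(-1, n).sum(axis=0)
            gbeta = g.reshape(-1, n).sum(axis=0)
            return ((x, gx.astype(data.dtype)), (gamma, ggamma), (beta, gbeta))

        out_data = xhat * gamma.data + beta.data
        out = Tensor(out_data.astype(data.dtype))
        if x.requires_grad or gamma.requires_grad or beta.requires_grad:
            out.requires_grad = True
            out._parents = (x, gamma, beta)
            out._backward = backward
        return out


class LSTM(Module):
    """Grouped LSTM: ``groups`` independent recurrences share one time loop.

    Standard gating: ``i, f, o`` sigmoid gates, candidate ``g = tanh``,
    ``C_t = f*C_{t-1} + i*g``, ``h_t = o*tanh(C_t)``, with ``h_0 = C_0 = 0``.
    Forward and backward are fused into one graph node; the backward pass is
    explicit backpropagation through time. With ``groups == 1`` input/output
    are (batch, steps, features); with G > 1 they are (G, batch, steps,
    features) and each group uses its own parameter slice — this is how the
    two directions of a bidirectional pass (and parallel towers) run without
    multiplying the Python-level step loop.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 groups: int = 1):
        super().__init__()
        self.hidden_size = hidden_size
        self.groups = groups
        bound = 1.0 / np.sqrt(hidden_size)
        self.W = uniform_init(rng, (groups, input_size, 4 * hidden_size), bound)
        self.U = uniform_init(rng, (groups, hidden_size, 4 * hidden_size), bound)
        self.b = uniform_init(rng, (groups, 1, 4 * hidden_size), bound)

    def __call__(self, x: Tensor) -> Tensor:
        squeeze = x.ndim == 3
        data = x.data[None] if squeeze else x.data
        G, B, T, _ = data.shape
        if G != self.groups:
            raise ValueError(f"expected {self.groups} groups, got {G}")
        H = self.hidden_size
        W, U, b = self.W, self.U, self.b
        # (G, B, T, 4H); W gains a broadcast axis so groups align with G, not B
        xw = data @ W.data[:, None] + b.data[:, None]
        dt = data.dtype
        gates = np.empty((T, G, B, 4 * H), dtype=dt)
        cells = np.empty((T, G, B, H), dtype=dt)
        tanhc = np.empty((T, G, B, H), dtype=dt)
        hprev = np.empty((T, G, B, H), dtype=dt)
        hs = np.empty((G, B, T, H), dtype=dt)
        jit = _HAVE_NUMBA and dt == np.float32
        if jit:
            _lstm_forward_kernel(
                np.ascontiguousarray(xw), U.data, gates, cells, tanhc, hprev, hs
            )
        else:
            h = np.zeros((G, B, H), dtype=dt)
            c = np.zeros((G, B, H), dtype=dt)
            for t in range(T):
                hprev[t] = h
                z = xw[:, :, t, :] + h @ U.data
                i = 1.0 / (1.0 + np.exp(-z[..., :H]))
                f = 1.0 / (1.0 + np.exp(-z[..., H : 2 * H]))
                g = np.tanh(z[..., 2 * H : 3 * H])
                o = 1.0 / (1.0 + np.exp(-z[..., 3 * H :]))
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                gates[t, ..., :H] = i
                gates[t, ..., H : 2 * H] = f
                gates[t, ..., 2 * H : 3 * H] = g
                gates[t, ..., 3 * H :] = o
                cells[t] = c
                tanhc[t] = tc
                hs[:, :, t, :] = h

        def backward(gout):
            gdata = gout[None] if squeeze else gout
            dW = np.zeros_like(W.data)
            dU = np.zeros_like(U.data)
            db = np.zeros_like(b.data)
            dx = np.zeros(data.shape, dtype=dt)
            if jit:
                _lstm_backward_kernel(
                    np.ascontiguousarray(gdata),
                    np.ascontiguousarray(data),
                    W.data, U.data, gates, cells, tanhc, hprev,
                    dW, dU, db, dx,
                )
            else:
                dh = np.zeros((G, B, H), dtype=dt)
                dc = np.zeros((G, B, H), dtype=dt)
                for t in range(T - 1, -1, -1):
                    i = gates[t, ..., :H]
                    f = gates[t, ..., H : 2 * H]
                    g = gates[t, ..., 2 * H : 3 * H]
                    o = gates[t, ..., 3 * H :]
                    tc = tanhc[t]
                    cprev = cells[t - 1] if t > 0 else np.zeros((G, B, H), dtype=dt)
                    dht = dh + gdata[:, :, t, :]
                    do = dht * tc
                    dc = dc + dht * o * (1.0 - tc**2)
                    di = dc * g
                    dg = dc * i
                    df = dc * cprev
                    dz = np.concatenate(
                        [
                            di * i * (1.0 - i),
                            df * f * (1.0 - f),
                            dg * (1.0 - g**2),
                            do * o * (1.0 - o),
                        ],
                        axis=-1,
                    )
                    dW += np.swapaxes(data[:, :, t, :], -1, -2) @ dz
                    dU += np.swapaxes(hprev[t], -1, -2) @ dz
                    db += dz.sum(axis=1, keepdims=True)
                    dx[:, :, t, :] = dz @ np.swapaxes(W.data, -1, -2)
                    dh = dz @ np.swapaxes(U.data, -1, -2)
                    dc = dc * f
            if squeeze:
                dx = dx[0]
            return ((x, dx), (W, dW), (U, dU), (b, db))

        out = Tensor(hs[0] if squeeze else hs)
        if x.requires_grad or W.requires_grad:
            out.requires_grad = True
            out._parents = (x, W, U, b)
            out._backward = backward
        return out
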