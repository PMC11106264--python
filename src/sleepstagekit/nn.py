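"""Minimal NumPy neural-network engine with manual backpropagation.

Provides exactly the layers the sleep stager needs: 1D convolution
(im2col + BLAS matmul), batch normalisation, ReLU, dropout, linear layers,
pre-activation residual blocks, global average pooling over time, a
bidirectional LSTM (explicit backprop through time) and an Adam optimiser.
Everything is float64 and deterministic given a ``numpy.random.Generator``.

The engine favours clarity and testability over speed: each layer caches
its forward inputs and implements ``backward`` by the textbook gradient
formulas, which are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x, train: bool = True):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d(Layer):
    """1D convolution on (N, C, L) via im2col."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad=None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init
        self.W = Param(rng.normal(scale=scale, size=(c_in * kernel, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def out_len(self, L):
        return (L + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=True):
        N, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        Lout = self.out_len(L)
        idx = self.stride * np.arange(Lout)[:, None] + np.arange(self.k)[None, :]
        cols = xp[:, :, idx]  # (N, C, Lout, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(N * Lout, C * self.k)
        out = cols @ self.W.value + self.b.value
        self._cache = (cols, x.shape, xp.shape[-1])
        return out.reshape(N, Lout, self.c_out).transpose(0, 2, 1)

    def backward(self, dout):
        cols, (N, C, L), Lp = self._cache
        Lout = dout.shape[-1]
        dflat = dout.transpose(0, 2, 1).reshape(N * Lout, self.c_out)
        self.W.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(N, Lout, C, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((N, C, Lp))
        pos0 = self.stride * np.arange(Lout)
        for kk in range(self.k):
            dxp[:, :, pos0 + kk] += dcols[:, :, :, kk]
        return dxp[:, :, self.pad : self.pad + L] if self.pad else dxp


class BatchNorm1d(Layer):
    """Per-channel normalisation over batch and time axes of (N, C, L)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        # exponential moving averages with bias correction, so evaluation-mode
        # statistics are usable after only a handful of training batches
        self.run_mean = np.zeros(channels)
        self.run_var = np.zeros(channels)
        self.n_updates = 0

    def params(self):
        return [self.gamma, self.beta]

    def running_stats(self):
        if self.n_updates == 0:
            return np.zeros_like(self.run_mean), np.ones_like(self.run_var)
        corr = 1.0 - self.momentum**self.n_updates
        return self.run_mean / corr, self.run_var / corr

    def forward(self, x, train=True):
        g = self.gamma.value[None, :, None]
        b = self.beta.value[None, :, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self.n_updates += 1
        else:
            mean, var = self.running_stats()
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, train)
        return g * xhat + b

    def backward(self, dout):
        xhat, ivar, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        dxhat = dout * g
        if not train:
            return dxhat * ivar[None, :, None]
        m = xhat.shape[0] * xhat.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivar[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class CenterTime(Layer):
    """Subtract the per-channel mean over time of each window.

    Acts as a high-pass step: the quasi-constant gravity offset of a 30-s
    window is removed while movement amplitude is preserved (no variance
    scaling), so rectifying nonlinearities downstream can read movement
    energy directly.
    """

    def forward(self, x, train=True):
        return x - x.mean(axis=-1, keepdims=True)

    def backward(self, dout):
        return dout - dout.mean(axis=-1, keepdims=True)


class Dropout(Layer):
    def __init__(self, p, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(scale=np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=True):
        self._L = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class PreActBlock1d(Layer):
    """Pre-activation residual block: BN-ReLU-Conv, BN-ReLU-Conv + shortcut.

    The shortcut is the identity when shapes match, otherwise a strided
    1x1 convolution of the block input.
    """

    def __init__(self, c_in, c_out, kernel=5, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.body = Sequential(
            BatchNorm1d(c_in),
            ReLU(),
            Conv1d(c_in, c_out, kernel, stride=stride, rng=rng),
            BatchNorm1d(c_out),
            ReLU(),
            Conv1d(c_out, c_out, kernel, stride=1, rng=rng),
        )
        if stride != 1 or c_in != c_out:
            self.shortcut = Conv1d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
        else:
            self.shortcut = None

    def params(self):
        ps = self.body.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x, train=True):
        out = self.body.forward(x, train=train)
        skip = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return out + skip

    def backward(self, dout):
        dx = self.body.backward(dout)
        if self.shortcut is None:
            return dx + dout
        return dx + self.shortcut.backward(dout)


class _LSTMDirection:
    def __init__(self, d_in, hidden, rng):
        s_x = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / hidden)
        self.Wx = Param(rng.normal(scale=s_x, size=(d_in, 4 * hidden)))
        self.Wh = Param(rng.normal(scale=s_h, size=(hidden, 4 * hidden)))
        self.b = Param(np.zeros(4 * hidden))
        self.b.value[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.H = hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        N, T, D = x.shape
        H = self.H
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._cache = []
        out = np.empty((N, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            out[:, t] = h
            self._cache.append((x[:, t], h_prev, c_prev, i, f, g, o, c))
        return out

    def backward(self, dh_all):
        N, T, H = dh_all.shape
        dx = np.empty((N, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c = self._cache[t]
            dh = dh_all[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += x_t.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: (N, T, D) -> (N, T, 2H) (forward || backward)."""

    def __init__(self, d_in, hidden, rng=None):
        rng = rng or np.random.default_rng(0)
        self.fwd = _LSTMDirection(d_in, hidden, rng)
        self.bwd = _LSTMDirection(d_in, hidden, rng)
        self.H = hidden

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, train=True):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        H = self.H
        dxf = self.fwd.backward(dout[:, :, :H])
        dxb = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dxf + dxb


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, targets, class_weights=None):
    """Mean weighted cross-entropy; returns (loss, dlogits).

    ``logits``: (M, K); ``targets``: (M,) int.  ``class_weights`` rescales
    each example's contribution by its class weight (mean-normalised).
    """
    M = logits.shape[0]
    p = softmax(logits)
    w = np.ones(M) if class_weights is None else np.asarray(class_weights)[targets]
    wsum = w.sum()
    ll = -np.log(np.maximum(p[np.arange(M), targets], 1e-12))
    loss = float((w * ll).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(M), targets] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def iter_layers(layer: Layer):
    """Depth-first traversal of a layer tree (containers included)."""
    yield layer
    if isinstance(layer, Sequential):
        for l in layer.layers:
            yield from iter_layers(l)
    elif isinstance(layer, PreActBlock1d):
        yield from iter_layers(layer.body)
        if layer.shortcut is not None:
            yield from iter_layers(layer.shortcut)


def n_parameters(layer: Layer) -> int:
    return int(sum(p.value.size for p in layer.params()))


def get_full_state(layer: Layer) -> dict:
    """Trainable parameters plus batch-norm running statistics."""
    bn = [
        (l.run_mean.copy(), l.run_var.copy(), l.n_updates)
        for l in iter_layers(layer)
        if isinstance(l, BatchNorm1d)
    ]
    return {"params": get_state(layer), "bn": bn}


def set_full_state(layer: Layer, state: dict) -> None:
    set_state(layer, state["params"])
    bns = [l for l in iter_layers(layer) if isinstance(l, BatchNorm1d)]
    if len(bns) != len(state["bn"]):
        raise ValueError("batch-norm buffer count mismatch")
    for l, (rm, rv, t) in zip(bns, state["bn"]):
        l.run_mean[...] = rm
        l.run_var[...] = rv
        l.n_updates = int(t)


def get_state(layer: Layer) -> list:
    return [p.value.copy() for p in layer.params()]


def set_state(layer: Layer, state: list) -> None:
    ps = layer.params()
    if len(ps) != len(state):
        raise ValueError("state length mismatch")
    for p, v in zip(ps, state):
        if p.value.shape != v.shape:
            raise ValueError(f"shape mismatch: {p.value.shape} vs {v.shape}")
        p.value[...] = v
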