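"""Layers with explicit forward/backward passes.

Shapes follow the time-major batch convention of the field: sequence
layers take ``(N, L, d)``, flat layers ``(N, d)``.  Convolutions are
'valid' (no padding).  Every layer exposes ``params``/``grads`` dicts and
a closed-form ``param_count``; the fusion network's parameter accounting
is built purely from these counts.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def relu(z):
    return np.maximum(z, 0.0)


def _glorot(rng, shape, dtype):
    fan_in, fan_out = shape[-2], shape[-1]
    if len(shape) > 2:  # convolution kernels: receptive field times channels
        receptive = int(np.prod(shape[:-2]))
        fan_in, fan_out = receptive * shape[-2], receptive * shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


_ACTS = {
    "linear": (lambda z: z, lambda z, y: np.ones_like(z)),
    "relu": (relu, lambda z, y: (z > 0).astype(z.dtype)),
    "sigmoid": (sigmoid, lambda z, y: y * (1.0 - y)),
    "tanh": (np.tanh, lambda z, y: 1.0 - y * y),
}


class Layer:
    """Base: parameter bookkeeping plus the forward/backward contract."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, key, value):
        self.params[key] = value
        self.grads[key] = np.zeros_like(value)
        return value

    def zero_grads(self):
        for g in self.grads.values():
            g[...] = 0.0

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def output_shape(self):  # informational, for summaries
        return None


class Dense(Layer):
    """Affine map on ``(N, d_in)`` with one bias per unit."""

    def __init__(self, d_in, d_out, activation="linear", rng=None, name="dense",
                 dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.d_in, self.d_out, self.activation = name, d_in, d_out, activation
        self.W = self.add_param("W", _glorot(rng, (d_in, d_out), dtype))
        self.b = self.add_param("b", np.zeros(d_out, dtype=dtype))
        self._act, self._dact = _ACTS[activation]

    def forward(self, x):
        self._x = x
        self._z = x @ self.W + self.b
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy):
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.W.T


class TimeDense(Layer):
    """The same affine map applied independently at every timestep.

    Parameter count ``d_out * (d_in + 1)`` — identical to a flat dense layer,
    which is how framework summaries report it.
    """

    def __init__(self, d_in, d_out, activation="relu", rng=None, name="dense",
                 dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.d_in, self.d_out, self.activation = name, d_in, d_out, activation
        self.W = self.add_param("W", _glorot(rng, (d_in, d_out), dtype))
        self.b = self.add_param("b", np.zeros(d_out, dtype=dtype))
        self._act, self._dact = _ACTS[activation]

    def forward(self, x):  # x: (N, L, d_in)
        self._x = x
        self._z = x @ self.W + self.b
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy):
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += np.einsum("nli,nlo->io", self._x, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        return dz @ self.W.T


class HighwayGating(Layer):
    """Gated (highway-style) block over a full ``(L, d)`` sequence.

    Per timestep t:  ``g = sigmoid(x_t W_G + b_G[t])``,
    ``h = relu(x_t W_T + b_T[t])``, ``out_t = g*h + (1-g)*x_t``.

    The transform/gate weight matrices are shared across time (d x d each)
    but the biases are *per timestep* (L x d each), so the trainable count
    is ``2*(d^2 + L*d)``.  Output shape equals input shape, letting blocks
    stack.  Gate biases start negative so the block begins close to the
    identity (carry) behaviour.
    """

    def __init__(self, d, L, rng=None, name="highway", gate_bias_init=-1.0,
                 dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.d, self.L = name, d, L
        self.W_G = self.add_param("W_G", _glorot(rng, (d, d), dtype))
        self.W_T = self.add_param("W_T", _glorot(rng, (d, d), dtype))
        self.b_G = self.add_param("b_G", np.full((L, d), gate_bias_init, dtype=dtype))
        self.b_T = self.add_param("b_T", np.zeros((L, d), dtype=dtype))

    def param_count(self):
        return 2 * (self.d ** 2 + self.L * self.d)

    def forward(self, x):  # x: (N, L, d)
        self._x = x
        self._g = sigmoid(x @ self.W_G + self.b_G)
        self._zt = x @ self.W_T + self.b_T
        self._h = relu(self._zt)
        return self._g * self._h + (1.0 - self._g) * x

    def backward(self, dy):
        g, h, x = self._g, self._h, self._x
        dg = dy * (h - x)
        dzg = dg * g * (1.0 - g)
        dzt = dy * g * (self._zt > 0)
        self.grads["W_G"] += np.einsum("nli,nlo->io", x, dzg)
        self.grads["W_T"] += np.einsum("nli,nlo->io", x, dzt)
        self.grads["b_G"] += dzg.sum(axis=0)
        self.grads["b_T"] += dzt.sum(axis=0)
        return dzg @ self.W_G.T + dzt @ self.W_T.T + dy * (1.0 - g)


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state ``(N, units)``.

    Standard 4-gate recurrence (input, forget, cell, output ordering), one
    bias per gate unit: ``4 * units * (d_in + units + 1)`` parameters.
    Forget-gate bias initialised to 1.
    """

    def __init__(self, d_in, units, rng=None, name="lstm", reverse=False,
                 dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.d_in, self.units, self.reverse = name, d_in, units, reverse
        u = units
        self.W = self.add_param("W", _glorot(rng, (d_in, 4 * u), dtype))
        self.U = self.add_param("U", _glorot(rng, (u, 4 * u), dtype))
        b = np.zeros(4 * u, dtype=dtype)
        b[u:2 * u] = 1.0  # forget gate
        self.b = self.add_param("b", b)

    def forward(self, x, mask=None):  # x: (N, L, d_in), mask: (N, L) bool
        """Run the recurrence; masked-out steps carry h and c through unchanged.

        When ``mask`` is None, steps whose input vector is exactly zero are
        treated as padding and skipped (zero-masking), matching the
        all-zero-rows padding convention of the aligned sequences.
        """
        if mask is None:
            mask = np.abs(x).sum(axis=2) > 0
        if self.reverse:
            x = x[:, ::-1]
            mask = mask[:, ::-1]
        N, L, _ = x.shape
        u = self.units
        h = np.zeros((N, u), dtype=x.dtype)
        c = np.zeros((N, u), dtype=x.dtype)
        self._x = x
        self._mask = mask
        self._cache = []
        xW = x @ self.W  # (N, L, 4u) hoisted out of the loop
        for t in range(L):
            m = mask[:, t, None].astype(x.dtype)
            z = xW[:, t] + h @ self.U + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tanh_c, m))
            h = m * (o * tanh_c) + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        self._h_final = h
        return h

    def backward(self, dh_out):  # dh_out: (N, units)
        x, u = self._x, self.units
        N, L, _ = x.shape
        dh = dh_out.astype(x.dtype).copy()
        dc = np.zeros_like(dh)
        dz_all = np.empty((N, L, 4 * u), dtype=x.dtype)
        dU = self.grads["U"]
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c, m = self._cache[t]
            dh_m = dh * m           # gradient through the updated path
            dc_m = dc * m
            do = dh_m * tanh_c
            dc_t = dc_m + dh_m * o * (1.0 - tanh_c ** 2)
            di, df, dg = dc_t * g, dc_t * c_prev, dc_t * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dz_all[:, t] = dz
            dU += h_prev.T @ dz
            dh = dz @ self.U.T + dh * (1.0 - m)
            dc = dc_t * f + dc * (1.0 - m)
        self.grads["W"] += np.einsum("nli,nlo->io", x, dz_all)
        self.grads["b"] += dz_all.sum(axis=(0, 1))
        dx = dz_all @ self.W.T
        if self.reverse:
            dx = dx[:, ::-1]
        return dx


class BiLSTM(Layer):
    """Forward + backward LSTM; final hiddens concatenated to ``(N, 2*units)``.

    Exactly doubles the single-direction parameter count.
    """

    def __init__(self, d_in, units, rng=None, name="bilstm", dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.d_in, self.units = name, d_in, units
        self.fwd = LSTM(d_in, units, rng=rng, name=name + "_fwd", dtype=dtype)
        self.bwd = LSTM(d_in, units, rng=rng, name=name + "_bwd", reverse=True,
                        dtype=dtype)

    @property
    def params(self):
        return {**{"fwd_" + k: v for k, v in self.fwd.params.items()},
                **{"bwd_" + k: v for k, v in self.bwd.params.items()}}

    @params.setter
    def params(self, value):  # base __init__ assigns {}; sublayers own theirs
        pass

    @property
    def grads(self):
        return {**{"fwd_" + k: v for k, v in self.fwd.grads.items()},
                **{"bwd_" + k: v for k, v in self.bwd.grads.items()}}

    @grads.setter
    def grads(self, value):
        pass

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x, mask=None):
        return np.concatenate([self.fwd.forward(x, mask=mask),
                               self.bwd.forward(x, mask=mask)], axis=1)

    def backward(self, dy):
        u = self.units
        return self.fwd.backward(dy[:, :u]) + self.bwd.backward(dy[:, u:])


class Conv1D(Layer):
    """Valid 1-D convolution along time: ``(N, L, c_in) -> (N, L-k+1, f)``."""

    def __init__(self, c_in, filters, kernel=3, activation="relu", rng=None,
                 name="conv1d", dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.c_in, self.filters, self.kernel = name, c_in, filters, kernel
        self.W = self.add_param("W", _glorot(rng, (kernel, c_in, filters), dtype))
        self.b = self.add_param("b", np.zeros(filters, dtype=dtype))
        self._act, self._dact = _ACTS[activation]

    def forward(self, x):
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (N, Lo, c_in, k) -> z: (N, Lo, f)
        self._win = win
        self._z = np.einsum("nlck,kcf->nlf", win, self.W) + self.b
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy):
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += np.einsum("nlck,nlf->kcf", self._win, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        Lo = dz.shape[1]
        for k in range(self.kernel):
            dx[:, k:k + Lo] += dz @ self.W[k].T
        return dx


class Conv2D(Layer):
    """Valid 2-D convolution: ``(N, H, W[, c_in]) -> (N, Ho, Wo, f)``.

    A 3-D input is treated as a one-channel grid; ``backward`` returns a
    gradient with the same rank the input had.
    """

    def __init__(self, c_in, filters, kernel=(3, 3), activation="relu",
                 rng=None, name="conv2d", dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.name, self.c_in, self.filters, self.kernel = name, c_in, filters, kernel
        kh, kw = kernel
        self.W = self.add_param("W", _glorot(rng, (kh, kw, c_in, filters), dtype))
        self.b = self.add_param("b", np.zeros(filters, dtype=dtype))
        self._act, self._dact = _ACTS[activation]

    def forward(self, x):
        kh, kw = self.kernel
        self._squeeze_channel = x.ndim == 3
        if self._squeeze_channel:
            x = x[..., None]
        self._x_shape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        self._win = win  # (N, Ho, Wo, c_in, kh, kw)
        self._z = np.einsum("nhwcij,ijcf->nhwf", win, self.W) + self.b
        self._y = self._act(self._z)
        return self._y

    def backward(self, dy):
        kh, kw = self.kernel
        dz = dy * self._dact(self._z, self._y)
        self.grads["W"] += np.einsum("nhwcij,nhwf->ijcf", self._win, dz)
        self.grads["b"] += dz.sum(axis=(0, 1, 2))
        dx = np.zeros(self._x_shape, dtype=dz.dtype)
        Ho, Wo = dz.shape[1], dz.shape[2]
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + Ho, j:j + Wo] += np.einsum(
                    "nhwf,cf->nhwc", dz, self.W[i, j])
        return dx[..., 0] if self._squeeze_channel else dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time (trailing remainder dropped).

    Inputs shorter than the pool window pass through unchanged (effective
    pool 1), so deep conv stacks stay valid on short sequences.
    """

    def __init__(self, pool=2, name="maxpool1d"):
        super().__init__()
        self.name, self.pool = name, pool

    def forward(self, x):  # (N, L, C)
        p = self._p = min(self.pool, max(x.shape[1], 1))
        Lp = (x.shape[1] // p) * p
        self._in_shape = x.shape
        xr = x[:, :Lp].reshape(x.shape[0], Lp // p, p, x.shape[2])
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        N, L, C = self._in_shape
        p = self._p
        Lo = dy.shape[1]
        n_i, l_i, c_i = np.ogrid[:N, :Lo, :C]
        dxr = np.zeros((N, Lo, p, C), dtype=dy.dtype)
        dxr[n_i, l_i, self._argmax, c_i] = dy
        dx = np.zeros((N, L, C), dtype=dy.dtype)
        dx[:, :Lo * p] = dxr.reshape(N, Lo * p, C)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2-D max pooling on ``(N, H, W, C)``.

    The effective pool per axis shrinks to the axis length when the input
    is smaller than the window.
    """

    def __init__(self, pool=2, name="maxpool2d"):
        super().__init__()
        self.name, self.pool = name, pool

    def forward(self, x):
        N, H, W, C = x.shape
        ph = self._ph = min(self.pool, max(H, 1))
        pw = self._pw = min(self.pool, max(W, 1))
        Ho, Wo = H // ph, W // pw
        self._in_shape = x.shape
        xr = x[:, :Ho * ph, :Wo * pw].reshape(N, Ho, ph, Wo, pw, C)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, Ho, Wo, C, ph * pw)
        self._argmax = flat.argmax(axis=4)
        return flat.max(axis=4)

    def backward(self, dy):
        N, H, W, C = self._in_shape
        ph, pw = self._ph, self._pw
        Ho, Wo = dy.shape[1], dy.shape[2]
        dflat = np.zeros((N, Ho, Wo, C, ph * pw), dtype=dy.dtype)
        n_i, h_i, w_i, c_i = np.ogrid[:N, :Ho, :Wo, :C]
        dflat[n_i, h_i, w_i, c_i, self._argmax] = dy
        dx = np.zeros((N, H, W, C), dtype=dy.dtype)
        dx[:, :Ho * ph, :Wo * pw] = (
            dflat.reshape(N, Ho, Wo, C, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, Ho * ph, Wo * pw, C))
        return dx


class Flatten(Layer):
    def __init__(self, name="flatten"):
        super().__init__()
        self.name = name

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)
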