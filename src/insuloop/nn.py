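"""A small, deterministic NumPy neural-network engine.

Implements exactly the layer vocabulary the insulator-loop models need:
1-D convolution over one-hot sequence (full channel depth, optional dilation
and same-padding), batch normalization, leaky ReLU, dropout, global max
pooling, dense layers, bidirectional LSTM, a time-distributed linear map, and
an RMSprop trainer minimizing binary cross-entropy. Everything is float32 and
driven by a caller-supplied ``numpy.random.Generator`` so runs are
reproducible bit-for-bit.

Layers expose ``forward(x, training)`` and ``backward(dy)``; parameters and
their gradients live in ``layer.params`` / ``layer.grads`` keyed by name.
Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return float(loss), dz.reshape(-1, 1).astype(F32)


class Layer:
    """Base layer: stateless unless it declares params/grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


def _glorot_init(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"W": _he_init(rng, (n_in, n_out), n_in),
                       "b": np.zeros(n_out, dtype=F32)}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class Conv1D(Layer):
    """1-D convolution over (N, L, C) with full channel depth.

    ``same`` padding keeps the output length equal to the input length;
    otherwise output length is L - (k - 1) * dilation (valid).

    Two equivalent compute strategies: im2col + one GEMM when the channel
    depth is small (the one-hot input layer), otherwise a sum of k shifted
    GEMMs with the shifted input slices cached for the weight gradient —
    measurably the fastest variant on bandwidth-limited single-core hosts.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 same: bool = False):
        super().__init__()
        self.k, self.d, self.same = kernel, dilation, same
        self.c_in, self.c_out = c_in, c_out
        self.params = {"W": _he_init(rng, (kernel * c_in, c_out), kernel * c_in),
                       "b": np.zeros(c_out, dtype=F32)}
        self._im2col = c_in <= 8
        self.needs_input_grad = True  # disabled for input-adjacent layers

    def _pad_amounts(self):
        if not self.same:
            return 0, 0
        total = (self.k - 1) * self.d
        return total // 2, total - total // 2

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        left, right = self._pad_amounts()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0))) if left or right else x
        N, Lp, C = xp.shape
        Lout = Lp - (self.k - 1) * self.d
        self._Lp, self._Lout, self._N = Lp, Lout, N
        if self._im2col:
            idx = np.arange(Lout)[:, None] + np.arange(self.k)[None, :] * self.d
            cols = xp[:, idx, :].reshape(N * Lout, self.k * C)
            self._cols = cols
            y = cols @ self.params["W"]
            y += self.params["b"]
            return y.reshape(N, Lout, self.c_out)
        Wk = self.params["W"].reshape(self.k, C, self.c_out)
        self._slices = []
        y = None
        for j in range(self.k):
            off = j * self.d
            sl = np.ascontiguousarray(
                xp[:, off:off + Lout, :]).reshape(N * Lout, C)
            self._slices.append(sl)  # reused for the weight gradient
            term = sl @ Wk[j]
            y = term if y is None else y.__iadd__(term)
        y += self.params["b"]
        return y.reshape(N, Lout, self.c_out)

    def backward(self, dy):
        Lp, Lout, N = self._Lp, self._Lout, self._N
        dy2 = np.ascontiguousarray(dy, dtype=F32).reshape(N * Lout, self.c_out)
        left, right = self._pad_amounts()
        if self._im2col:
            dW = self._cols.T @ dy2
        else:
            dW = np.empty_like(self.params["W"])
            for j in range(self.k):
                dW[j * self.c_in:(j + 1) * self.c_in] = self._slices[j].T @ dy2
        self.grads = {"W": dW, "b": dy2.sum(axis=0)}
        if not self.needs_input_grad:
            return None
        dxp = np.zeros((N, Lp, self.c_in), dtype=F32)
        Wk = self.params["W"].reshape(self.k, self.c_in, self.c_out)
        for j in range(self.k):
            off = j * self.d
            dxp[:, off:off + Lout, :] += (dy2 @ Wk[j].T).reshape(N, Lout,
                                                                 self.c_in)
        return dxp[:, left:Lp - right, :] if (left or right) else dxp


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis of (N, C) or (N, L, C)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels, dtype=F32),
                       "beta": np.zeros(channels, dtype=F32)}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = x - mean
        xhat *= self._inv
        self._xhat = xhat
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._training = training
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, dy):
        xhat, inv, axes, n = self._xhat, self._inv, self._axes, self._n
        s_beta = dy.sum(axis=axes)
        prod = dy * xhat
        s_gamma = prod.sum(axis=axes)
        self.grads = {"gamma": s_gamma, "beta": s_beta}
        g = self.params["gamma"]
        if not self._training:
            return dy * (g * inv)
        # dx = (g*inv) * (dy - s_beta/n - xhat * s_gamma/n), fused to limit
        # full-size temporaries on bandwidth-bound hosts
        dx = xhat * (s_gamma * (-1.0 / n))
        dx += dy
        dx -= s_beta * (1.0 / n)
        dx *= g * inv
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False):
        # arithmetic mask: np.where is pathologically slow on this host class
        factor = (x >= 0).astype(F32)
        factor *= np.float32(1.0 - self.slope)
        factor += np.float32(self.slope)
        self._factor = factor
        return x * factor

    def backward(self, dy):
        dy = dy * self._factor if dy.base is not None else dy.__imul__(self._factor)
        return dy


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(F32)
        mask /= keep
        self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalMaxPool(Layer):
    """Max over the time axis of (N, L, C) -> (N, C)."""

    def forward(self, x, training=False):
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=F32)
        n_idx = np.arange(self._shape[0])[:, None]
        c_idx = np.arange(self._shape[2])[None, :]
        dx[n_idx, self._arg, c_idx] = dy
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class TimeDistributedDense(Layer):
    """Per-position linear map over (N, T, C) -> (N, T, units)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"W": _glorot_init(rng, (n_in, units)),
                       "b": np.zeros(units, dtype=F32)}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": np.einsum("ntc,ntu->cu", self._x, dy, optimize=True),
                      "b": dy.sum(axis=(0, 1))}
        return dy @ self.params["W"].T


class LSTM(Layer):
    """Unidirectional LSTM over (N, T, C) returning the full state sequence.

    Gate order i, f, g, o; forget-gate bias initialized to 1. ``reverse``
    processes the sequence right-to-left (output re-reversed to input order).
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        self.units, self.n_in, self.reverse = units, n_in, reverse
        self.params = {"Wx": _glorot_init(rng, (n_in, 4 * units)),
                       "Wh": _glorot_init(rng, (units, 4 * units)),
                       "b": np.zeros(4 * units, dtype=F32)}
        self.params["b"][units:2 * units] = 1.0  # forget gate

    def forward(self, x, training=False):
        x = x.astype(F32, copy=False)
        if self.reverse:
            x = x[:, ::-1, :]
        N, T, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((N, u), dtype=F32)
        c = np.zeros((N, u), dtype=F32)
        xw = x @ Wx + b  # precompute input contribution for all steps
        H = np.empty((N, T, u), dtype=F32)
        cache = []
        for t in range(T):
            z = xw[:, t, :] + h @ Wh
            i = sigmoid(z[:, :u]).astype(F32)
            f = sigmoid(z[:, u:2 * u]).astype(F32)
            g = np.tanh(z[:, 2 * u:3 * u]).astype(F32)
            o = sigmoid(z[:, 3 * u:]).astype(F32)
            c_new = f * c + i * g
            tc = np.tanh(c_new).astype(F32)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            H[:, t, :] = h
        self._cache, self._x = cache, x
        return H[:, ::-1, :] if self.reverse else H

    def backward(self, dH):
        if self.reverse:
            dH = dH[:, ::-1, :]
        x, cache = self._x, self._cache
        N, T, _ = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((N, u), dtype=F32)
        dc_next = np.zeros((N, u), dtype=F32)
        dZ = np.empty((N, T, 4 * u), dtype=F32)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dZ[:, t, :] = dz
            dh_next = dz @ Wh.T
            dWh += h_prev.T @ dz
        dWx = np.einsum("ntc,ntz->cz", x, dZ, optimize=True)
        db = dZ.sum(axis=(0, 1))
        dx = dZ @ Wx.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx[:, ::-1, :] if self.reverse else dx


class BiLSTM(Layer):
    """Bidirectional LSTM: concatenated forward and backward state sequences."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(n_in, units, rng)
        self.bwd = LSTM(n_in, units, rng, reverse=True)
        self.units = units

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x, training=False):
        return np.concatenate([self.fwd.forward(x, training),
                               self.bwd.forward(x, training)], axis=2)

    def backward(self, dy):
        u = self.units
        return (self.fwd.backward(dy[:, :, :u])
                + self.bwd.backward(dy[:, :, u:]))


class ParallelConcat(Layer):
    """Apply branches to the same input, concatenate outputs on channel axis."""

    def __init__(self, branches: list[Layer]):
        super().__init__()
        self.branches = branches

    @property
    def sublayers(self):
        return list(self.branches)

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, dy):
        dx = None
        offset = 0
        for b, w in zip(self.branches, self._widths):
            d = b.backward(dy[..., offset:offset + w])
            dx = d if dx is None else dx + d
            offset += w
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def sublayers(self):
        return list(self.layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

def iter_layers(root: Layer):
    """Depth-first iteration over a layer tree."""
    yield root
    for sub in getattr(root, "sublayers", []):
        yield from iter_layers(sub)


def named_params(roots: dict[str, Layer]) -> dict[str, np.ndarray]:
    """Flatten parameters (and batchnorm running stats) of named layer trees."""
    flat: dict[str, np.ndarray] = {}
    for name, root in roots.items():
        for i, layer in enumerate(iter_layers(root)):
            for pname, val in layer.params.items():
                flat[f"{name}/{i}/{pname}"] = val
            if isinstance(layer, BatchNorm):
                flat[f"{name}/{i}/running_mean"] = layer.running_mean
                flat[f"{name}/{i}/running_var"] = layer.running_var
    return flat


def load_params(roots: dict[str, Layer], flat: dict[str, np.ndarray]) -> None:
    for name, root in roots.items():
        for i, layer in enumerate(iter_layers(root)):
            for pname in layer.params:
                layer.params[pname] = flat[f"{name}/{i}/{pname}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = flat[f"{name}/{i}/running_mean"].copy()
                layer.running_var = flat[f"{name}/{i}/running_var"].copy()


def set_rng(root: Layer, rng: np.random.Generator) -> None:
    for layer in iter_layers(root):
        layer.rng = rng


class RMSprop:
    """RMSprop with the standard running-average-of-squares rule.

    ``clip_norm`` rescales each step's full gradient to at most that global
    L2 norm before the update (0 disables clipping).
    """

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7,
                 clip_norm: float = 0.0):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.clip_norm = clip_norm
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, trainable: list[Layer]) -> None:
        scale = None
        if self.clip_norm:
            total = 0.0
            for layer in trainable:
                for grad in layer.grads.values():
                    total += float(np.sum(grad.astype(np.float64) ** 2))
            norm = np.sqrt(total)
            if norm > self.clip_norm:
                scale = F32(self.clip_norm / norm)
        for layer in trainable:
            if not layer.trainable or not layer.grads:
                continue
            cache = self._cache.setdefault(id(layer), {})
            for pname, grad in layer.grads.items():
                grad = grad.astype(F32)
                if scale is not None:
                    grad = grad * scale
                v = cache.get(pname)
                if v is None:
                    v = np.zeros_like(layer.params[pname], dtype=F32)
                v = self.rho * v + (1 - self.rho) * grad ** 2
                cache[pname] = v
                layer.params[pname] -= (self.lr * grad
                                        / (np.sqrt(v) + self.eps)).astype(F32)
            layer.grads = {}
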