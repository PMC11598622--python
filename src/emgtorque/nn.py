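"""Minimal NumPy neural-network stack for the windowed torque regressors.

Implements exactly the layers the four architectures need — fully connected
(optionally time-distributed), 3x3 same-padding 2-D convolution, batch
normalisation, 2x2 average pooling, dropout, and an LSTM — together with
Glorot-uniform initialisation, mean-squared-error loss and an Adam
optimizer with a stepwise learning-rate drop schedule.  Forward and
backward passes are hand-written and verified against finite differences
in the test suite.

Conventions: batches are leading-axis; convolutional features are
``[N, H, W, C]``; sequences are ``[N, T, F]``.  All randomness (init,
shuffling, dropout) flows through explicit ``numpy.random.Generator``
objects, so identical seeds give identical parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "ReLU", "Conv2D", "BatchNorm", "AvgPool2D", "Dropout",
    "Flatten", "ToSequence", "LSTM", "Network", "Adam", "glorot_uniform",
]


def glorot_uniform(rng, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base: parameters/gradients are name -> array dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map; 3-D input ``[N, T, F]`` is applied per timestep."""

    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        self._x2 = x.reshape(-1, self.n_in)
        y = self._x2 @ self.params["W"] + self.params["b"]
        return y.reshape(self._shape[:-1] + (self.n_out,))

    def backward(self, g):
        g2 = g.reshape(-1, self.n_out)
        self.grads = {"W": self._x2.T @ g2, "b": g2.sum(axis=0)}
        return (g2 @ self.params["W"].T).reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv2D(Layer):
    """3x3 (by default) stride-1 convolution with same zero padding."""

    def __init__(self, c_in, c_out, rng, kernel=3, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.params = {
            "W": glorot_uniform(rng, (fan_in, c_out), fan_in, fan_out, dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def _cols(self, xp, H, W):
        # [N, H, W, C, k, k] view -> [N*H*W, k*k*C] with (ki, kj, c) ordering
        v = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        v = v.transpose(0, 1, 2, 4, 5, 3)  # N,H,W,ki,kj,C
        return np.ascontiguousarray(v).reshape(-1, self.k * self.k * self.c_in)

    def forward(self, x, train=False, rng=None):
        N, H, W, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xshape, self._cols_cache = x.shape, self._cols(xp, H, W)
        y = self._cols_cache @ self.params["W"] + self.params["b"]
        return y.reshape(N, H, W, self.c_out)

    def backward(self, g):
        N, H, W, _ = self._xshape
        p, k, C = self.k // 2, self.k, self.c_in
        g2 = g.reshape(-1, self.c_out)
        self.grads = {"W": self._cols_cache.T @ g2, "b": g2.sum(axis=0)}
        dcols = (g2 @ self.params["W"].T).reshape(N, H, W, k, k, C)
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + H, p : p + W, :]


class AvgPool2D(Layer):
    """2x2 stride-2 average pooling with floor semantics; a dimension
    already collapsed to 1 passes through unpooled."""

    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        N, H, W, C = x.shape
        ph = self.pool if H >= self.pool else 1
        pw = self.pool if W >= self.pool else 1
        Ho, Wo = H // ph, W // pw
        self._meta = (x.shape, ph, pw, Ho, Wo)
        xt = x[:, : Ho * ph, : Wo * pw, :]
        return xt.reshape(N, Ho, ph, Wo, pw, C).mean(axis=(2, 4))

    def backward(self, g):
        (N, H, W, C), ph, pw, Ho, Wo = self._meta
        dx = np.zeros((N, H, W, C), dtype=g.dtype)
        expanded = np.repeat(np.repeat(g, ph, axis=1), pw, axis=2) / (ph * pw)
        dx[:, : Ho * ph, : Wo * pw, :] = expanded
        return dx

    @staticmethod
    def out_size(n: int, pool: int = 2) -> int:
        return n // pool if n >= pool else n


class BatchNorm(Layer):
    """Normalise over all but the last axis; per-feature scale and shift."""

    def __init__(self, n_features, dtype=np.float32, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        # bias-corrected EMA of batch statistics (correction avoids stale
        # zero/one estimates when only a few batches have been seen)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self._ema_mean = np.zeros(n_features, dtype=dtype)
        self._ema_var = np.zeros(n_features, dtype=dtype)
        self._n_updates = 0

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self._ema_mean = (1 - m) * self._ema_mean + m * mean
            self._ema_var = (1 - m) * self._ema_var + m * var
            self._n_updates += 1
            corr = 1.0 - (1.0 - m) ** self._n_updates
            self.running_mean = (self._ema_mean / corr).astype(self.running_mean.dtype)
            self.running_var = (self._ema_var / corr).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        axes = self._axes
        m = np.prod([g.shape[a] for a in axes])
        self.grads = {
            "gamma": (g * self._xhat).sum(axis=axes),
            "beta": g.sum(axis=axes),
        }
        gg = g * self.params["gamma"]
        return (
            gg - gg.mean(axis=axes) - self._xhat * (gg * self._xhat).mean(axis=axes)
        ) / self._std


class Dropout(Layer):
    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class ToSequence(Layer):
    """Reshape conv features ``[N, H, W, C]`` to sequences ``[N, H, W*C]``
    (rows become timesteps)."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        N, H, W, C = x.shape
        return x.reshape(N, H, W * C)

    def backward(self, g):
        return g.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state ``[N, units]``.

    Gate order is (input, forget, cell, output); the forget-gate bias is
    initialised to 1 (standard practice for gradient flow at the start of
    training).
    """

    def __init__(self, n_in, units, rng, dtype=np.float32):
        super().__init__()
        self.n_in, self.units = n_in, units
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0
        self.params = {
            "Wx": glorot_uniform(rng, (n_in, 4 * units), n_in, units, dtype),
            "Wh": glorot_uniform(rng, (units, 4 * units), units, units, dtype),
            "b": b,
        }

    def forward(self, x, train=False, rng=None):
        N, T, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((N, u), dtype=x.dtype)
        c = np.zeros((N, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, gout):
        x = self._x
        N, T, _ = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = gout.astype(x.dtype).copy()
        dc = np.zeros((N, u), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class Network:
    """An ordered stack of named layers with a scalar regression output."""

    def __init__(self, layers: list[tuple[str, Layer]], arch: str = "", input_shape=None):
        self.layers = layers
        self.arch = arch
        self.input_shape = tuple(input_shape) if input_shape is not None else None

    def __getitem__(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(name)

    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def forward(self, x, train=False, rng=None):
        for _, layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for _, layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict(self, X, batch_size=512):
        out = []
        for k in range(0, X.shape[0], batch_size):
            out.append(self.forward(X[k : k + batch_size], train=False)[:, 0])
        return np.concatenate(out) if out else np.empty(0)

    def parameters(self):
        """Yield (``layer.param``, array) pairs in order."""
        for name, layer in self.layers:
            for pname, arr in layer.params.items():
                yield f"{name}.{pname}", arr

    def gradients(self):
        for name, layer in self.layers:
            for pname, arr in layer.grads.items():
                yield f"{name}.{pname}", arr

    def get_weights(self) -> dict[str, np.ndarray]:
        """All parameters plus batch-norm running statistics, by name."""
        out = {k: v.copy() for k, v in self.parameters()}
        for name, layer in self.layers:
            if isinstance(layer, BatchNorm):
                out[f"{name}.running_mean"] = layer.running_mean.copy()
                out[f"{name}.running_var"] = layer.running_var.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            targets = dict(layer.params)
            if isinstance(layer, BatchNorm):
                targets["running_mean"] = layer.running_mean
                targets["running_var"] = layer.running_var
            for pname, dst in targets.items():
                key = f"{name}.{pname}"
                if key not in weights:
                    continue
                src = weights[key]
                if src.shape != dst.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {src.shape} vs {dst.shape}"
                    )
                arr = src.astype(dst.dtype).copy()
                if pname in layer.params:
                    layer.params[pname] = arr
                else:
                    setattr(layer, pname, arr)

    def n_parameters(self) -> int:
        return sum(int(np.prod(a.shape)) for _, a in self.parameters())

    def summary(self) -> str:
        lines = [f"{self.arch or 'network'} (input {self.input_shape})"]
        for name, layer in self.layers:
            shapes = ", ".join(f"{p}{list(a.shape)}" for p, a in layer.params.items())
            lines.append(f"  {name}: {type(layer).__name__}({shapes})")
        lines.append(f"  total parameters: {self.n_parameters()}")
        return "\n".join(lines)


class Adam:
    """Adam with a stepwise learning-rate drop (factor every drop period)."""

    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8,
                 drop_period=10, drop_factor=0.2):
        self.lr0, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.drop_period, self.drop_factor = drop_period, drop_factor
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.drop_factor ** (epoch // self.drop_period)

    def step(self, network: Network, epoch: int) -> None:
        lr = self.lr_at(epoch)
        self.t += 1
        grads = dict(network.gradients())
        for name, layer in network.layers:
            for pname, arr in layer.params.items():
                key = f"{name}.{pname}"
                g = grads.get(key)
                if g is None:
                    continue
                g = g.astype(arr.dtype)
                if key not in self.m:
                    self.m[key] = np.zeros_like(arr)
                    self.v[key] = np.zeros_like(arr)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                mhat = self.m[key] / (1 - self.beta1 ** self.t)
                vhat = self.v[key] / (1 - self.beta2 ** self.t)
                arr -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)
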