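"""NumPy neural-network layers with explicit backpropagation.

Each layer exposes ``forward(x, training, rng)`` and ``backward(grad)``;
parameters and their gradients live in ``params`` / ``grads`` dicts so an
optimizer can walk the whole network.  Shapes follow the channels-last
convention ``(batch, length, channels)`` for convolutional layers and
``(batch, time, features)`` for recurrent ones.

Gradient correctness is established by finite-difference checks in the
test suite; these layers are the substrate for the cross-modal
autoencoder and deliberately implement only what it needs (1-D "same"
convolution along time, valid average pooling, inverted dropout, LSTM
with full backpropagation through time, vector repetition and strided
transposed convolution).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "AvgPool1d",
    "ReLU",
    "Dropout",
    "LSTM",
    "RepeatVector",
    "ConvTranspose1d",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter registry plus the forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class Conv1d(Layer):
    """1-D convolution along the time axis, TensorFlow-style "same" padding.

    Output length is ``ceil(L / stride)``; the kernel slides over
    ``in_channels`` with weights of shape (kernel, in_channels, out_channels).
    """

    def __init__(self, in_channels, out_channels, kernel=7, stride=2,
                 rng=None, dtype=np.float32, input_grad=True,
                 cache_columns=False):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride = kernel, stride
        # first-layer convs can skip the (unused) input gradient and may
        # cache im2col output; caching assumes inputs are never mutated
        # in place between calls, which holds for the training loop
        self.input_grad = input_grad
        self.cache_columns = cache_columns
        limit = np.sqrt(6.0 / (kernel * in_channels + out_channels))
        self.params["W"] = rng.uniform(
            -limit, limit, (kernel, in_channels, out_channels)
        ).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._col_entries: list = []
        self.zero_grad()

    def out_len(self, L: int) -> int:
        return -(-L // self.stride)

    def _columns(self, x):
        """im2col; reused when the same array is fed repeatedly (full batch).

        The cache key is the identity of the underlying buffer (a strong
        reference is held, so it cannot be recycled) plus shape/strides;
        training never mutates its input tensor in place.
        """
        root = x.base if x.base is not None else x
        meta = (x.shape, x.strides, x.dtype)
        if self.cache_columns:
            for entry_root, entry_meta, entry in self._col_entries:
                if entry_root is root and entry_meta == meta:
                    return entry
        B, L, Cin = x.shape
        K, s = self.kernel, self.stride
        Lo = self.out_len(L)
        total_pad = max((Lo - 1) * s + K - L, 0)
        pl = total_pad // 2
        xp = np.zeros((B, L + total_pad, Cin), dtype=x.dtype)
        xp[:, pl : pl + L] = x
        idx = (np.arange(Lo) * s)[:, None] + np.arange(K)[None, :]
        cols = np.ascontiguousarray(xp[:, idx, :])  # (B, Lo, K, Cin)
        entry = (cols, pl, total_pad)
        if self.cache_columns:
            self._col_entries.append((root, meta, entry))
            del self._col_entries[:-2]  # keep train and validation tensors
        return entry

    def forward(self, x, training=False, rng=None):
        B, L, Cin = x.shape
        K = self.kernel
        cols, pl, total_pad = self._columns(x)
        Lo = cols.shape[1]
        self._cache = (cols, x.shape, pl, total_pad)
        W = self.params["W"].reshape(K * Cin, -1)
        y = cols.reshape(B, Lo, K * Cin) @ W + self.params["b"]
        return y

    def backward(self, grad):
        cols, (B, L, Cin), pl, total_pad = self._cache
        K, s = self.kernel, self.stride
        Lo = grad.shape[1]
        W = self.params["W"].reshape(K * Cin, -1)
        flat_cols = cols.reshape(B * Lo, K * Cin)
        flat_grad = grad.reshape(B * Lo, -1)
        self.grads["W"] += (flat_cols.T @ flat_grad).reshape(
            self.params["W"].shape
        )
        self.grads["b"] += flat_grad.sum(axis=0)
        if not self.input_grad:
            return None
        dcols = (flat_grad @ W.T).reshape(B, Lo, K, Cin)
        dxp = np.zeros((B, L + total_pad, Cin), dtype=grad.dtype)
        pos0 = np.arange(Lo) * s
        for kk in range(K):
            dxp[:, pos0 + kk, :] += dcols[:, :, kk, :]
        return dxp[:, pl : pl + L]


class AvgPool1d(Layer):
    """Valid average pooling along time; output (L - kernel)//stride + 1."""

    def __init__(self, kernel=2, stride=None):
        super().__init__()
        self.kernel = kernel
        self.stride = kernel if stride is None else stride

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        k, s = self.kernel, self.stride
        Lo = (L - k) // s + 1
        idx = (np.arange(Lo) * s)[:, None] + np.arange(k)[None, :]
        self._cache = (x.shape, idx)
        return x[:, idx, :].mean(axis=2)

    def backward(self, grad):
        (B, L, C), idx = self._cache
        k, s = self.kernel, self.stride
        Lo = grad.shape[1]
        dx = np.zeros((B, L, C), dtype=grad.dtype)
        g = grad / k
        pos0 = np.arange(Lo) * s
        for kk in range(k):
            dx[:, pos0 + kk, :] += g
        return dx


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p=0.2):
        super().__init__()
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class LSTM(Layer):
    """LSTM over (batch, time, features) with full BPTT.

    Gate order i, f, g, o; gates are logistic, the cell input and output
    nonlinearity is ``activation`` ("tanh" or "relu"; ReLU cells are
    numerically touchier).  ``init`` is either "small-uniform"
    (U[-0.05, 0.05], forget bias 1) or "unit-uniform" (all parameters
    U[0, 1]).
    """

    def __init__(self, input_size, hidden_size, return_sequences=True,
                 activation="tanh", init="small-uniform", rng=None,
                 dtype=np.float32, init_scale=0.05):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        if activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        self.activation = activation
        H = hidden_size
        if init == "small-uniform":
            a = init_scale
            self.params["W"] = rng.uniform(
                -a, a, (input_size, 4 * H)).astype(dtype)
            self.params["U"] = rng.uniform(
                -a, a, (H, 4 * H)).astype(dtype)
            b = np.zeros(4 * H, dtype=dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params["b"] = b
        elif init == "unit-uniform":
            self.params["W"] = rng.uniform(
                0.0, 1.0, (input_size, 4 * H)).astype(dtype)
            self.params["U"] = rng.uniform(
                0.0, 1.0, (H, 4 * H)).astype(dtype)
            self.params["b"] = rng.uniform(0.0, 1.0, 4 * H).astype(dtype)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.zero_grad()

    def _act(self, x):
        return np.tanh(x) if self.activation == "tanh" else np.maximum(x, 0)

    def forward(self, x, training=False, rng=None):
        B, T, D = x.shape
        H = self.hidden_size
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        xw = x.reshape(B * T, D) @ W  # precomputed input projections
        xw = xw.reshape(B, T, 4 * H) + b
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        gates, cells, acts, hs = [], [], [], []
        for t in range(T):
            z = xw[:, t] + h @ U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = self._act(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            a_c = self._act(c)
            h = o * a_c
            gates.append((i, f, g, o))
            cells.append(c)
            acts.append(a_c)
            hs.append(h)
        self._cache = (x, gates, cells, acts, hs)
        if self.return_sequences:
            return np.stack(hs, axis=1)
        return hs[-1]

    def backward(self, grad):
        x, gates, cells, acts, hs = self._cache
        B, T, D = x.shape
        H = self.hidden_size
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o = gates[t]
            c = cells[t]
            a_c = acts[t]
            c_prev = cells[t - 1] if t > 0 else np.zeros_like(c)
            h_prev = hs[t - 1] if t > 0 else np.zeros_like(dh_next)
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad[:, t]
            elif t == T - 1:
                dh += grad
            do = dh * a_c
            if self.activation == "tanh":
                dc = dc_next + dh * o * (1.0 - a_c * a_c)
                dg_pre = (1.0 - g * g)
            else:
                dc = dc_next + dh * o * (c > 0)
                dg_pre = (g > 0).astype(x.dtype)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * dg_pre,
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return dx


class RepeatVector(Layer):
    """(B, H) -> (B, n, H); backward sums over the repeats."""

    def __init__(self, n: int):
        super().__init__()
        self.n = n

    def forward(self, x, training=False, rng=None):
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, grad):
        return grad.sum(axis=1)


class ConvTranspose1d(Layer):
    """Strided transposed 1-D convolution (time upsampling).

    Output length is ``(L - 1) * stride + kernel``; with kernel = stride = 2
    the length exactly doubles, matching the decoder's 5 -> 10 -> 20 chain.
    """

    def __init__(self, in_channels, out_channels, kernel=2, stride=2,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride = kernel, stride
        limit = np.sqrt(6.0 / (kernel * in_channels + out_channels))
        self.params["W"] = rng.uniform(
            -limit, limit, (kernel, in_channels, out_channels)
        ).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def out_len(self, L: int) -> int:
        return (L - 1) * self.stride + self.kernel

    def forward(self, x, training=False, rng=None):
        B, L, Cin = x.shape
        K, s = self.kernel, self.stride
        Lo = self.out_len(L)
        Cout = self.params["b"].shape[0]
        y = np.zeros((B, Lo, Cout), dtype=x.dtype)
        pos0 = np.arange(L) * s
        for kk in range(K):
            y[:, pos0 + kk, :] += x @ self.params["W"][kk]
        y += self.params["b"]
        self._cache = x
        return y

    def backward(self, grad):
        x = self._cache
        B, L, Cin = x.shape
        K, s = self.kernel, self.stride
        dx = np.zeros_like(x)
        pos0 = np.arange(L) * s
        xf = x.reshape(B * L, Cin)
        for kk in range(K):
            gslice = grad[:, pos0 + kk, :]  # (B, L, Cout)
            self.grads["W"][kk] += xf.T @ gslice.reshape(B * L, -1)
            dx += gslice @ self.params["W"][kk].T
        self.grads["b"] += grad.sum(axis=(0, 1))
        return dx
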