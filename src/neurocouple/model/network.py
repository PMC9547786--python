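"""The cross-modal CNN-LSTM sequence-to-sequence autoencoder.

Architecture (per-sample shapes for the default configuration, EEG
sequence length S, fNIRS sequence length Sf, 21 EEG channels, 500 points
per element):

====================  =======================
layer                 output
====================  =======================
input                 (S, 500, 21)
conv block 1          (S, 125, F1)
conv block 2          (S, 62, F2)
reshape               (S, 62*F2)
encoder LSTM 1        (S, 512)
encoder LSTM 2        (1, 256)   latent
repeat                (Sf, 256)
decoder LSTM 3        (Sf, 312)
decoder LSTM 4        (Sf, 695)
reshape               (Sf, 5, 139)
deconvolution 1       (Sf, 10, F4)
deconvolution 2       (Sf, 20, n_fnirs_channels)
====================  =======================

Each conv block is a stride-(1,2) kernel-(1,7) convolution with ReLU,
dropout and average pooling; the first block pools with stride 2
(500 -> 250 -> 125), the second with stride 1 (125 -> 63 -> 62), which is
the unique pooling arithmetic that reproduces the 125/62 milestone sizes.
The latent vector is the final hidden state of encoder LSTM 2.  The
deconvolutions use kernel (1,2), stride (1,2); the last one is linear so
the mean-centered targets' negative values are reachable.

Training is plain stochastic gradient descent via backpropagation
through time (learning rate 0.05, batch 60, 50 epochs by default) with
the gradient's global norm clipped to 1.0.  The estimator follows the
scikit-learn protocol: ``fit(X, y)`` / ``predict(X)``, hyperparameters in
``__init__``, fitted state in trailing-underscore attributes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .layers import (
    AvgPool1d,
    Conv1d,
    ConvTranspose1d,
    Dropout,
    LSTM,
    ReLU,
    RepeatVector,
)

__all__ = ["CrossModalAutoencoder", "TrainReport"]


@dataclass
class TrainReport:
    """Per-epoch loss curves and the sample split of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    wall_time_s: float = 0.0
    n_parameters: int = 0


class _Net:
    """Layer container wiring the encoder/decoder chain."""

    def __init__(self, seq_len, eeg_points, n_eeg_channels, fnirs_seq_len,
                 fnirs_points, n_fnirs_channels, feature_maps, decoder_maps,
                 lstm_units, conv_kernel, conv_stride, pool_kernel, dropout,
                 activation, init, rng, dtype, init_scale=0.05):
        f1, f2 = feature_maps
        u1, u2, u3, u4 = lstm_units
        self.seq_len = seq_len
        self.fnirs_seq_len = fnirs_seq_len
        self.fnirs_points = fnirs_points
        self.n_fnirs_channels = n_fnirs_channels

        self.conv1 = Conv1d(n_eeg_channels, f1, conv_kernel, conv_stride,
                            rng, dtype, input_grad=False, cache_columns=True)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout)
        self.pool1 = AvgPool1d(pool_kernel, pool_kernel)
        self.conv2 = Conv1d(f1, f2, conv_kernel, conv_stride, rng, dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout)
        self.pool2 = AvgPool1d(pool_kernel, 1)

        len1 = (self.conv1.out_len(eeg_points) - pool_kernel) // pool_kernel + 1
        len2 = self.conv2.out_len(len1) - pool_kernel + 1
        self.conv_out_len = (len1, len2)
        flat = len2 * f2

        self.lstm1 = LSTM(flat, u1, True, activation, init, rng, dtype,
                          init_scale)
        self.drop3 = Dropout(dropout)
        self.lstm2 = LSTM(u1, u2, False, activation, init, rng, dtype,
                          init_scale)
        self.repeat = RepeatVector(fnirs_seq_len)
        self.lstm3 = LSTM(u2, u3, True, activation, init, rng, dtype,
                          init_scale)
        self.drop4 = Dropout(dropout)
        self.lstm4 = LSTM(u3, u4, True, activation, init, rng, dtype,
                          init_scale)
        self.drop5 = Dropout(dropout)

        # decoder reshape: (Sf, base, F3) with two kernel-2 stride-2 upsamples
        base = fnirs_points // 4
        if base * 4 != fnirs_points:
            raise ValueError(
                "fnirs points per element must be divisible by 4 "
                "(two stride-2 deconvolutions)"
            )
        if u4 % base != 0:
            raise ValueError(
                f"decoder width {u4} not divisible by the reshape base {base}"
            )
        self.decoder_base = base
        self.decoder_f3 = u4 // base
        self.deconv1 = ConvTranspose1d(self.decoder_f3, decoder_maps, 2, 2,
                                       rng, dtype)
        self.relu3 = ReLU()
        self.drop6 = Dropout(dropout)
        self.deconv2 = ConvTranspose1d(decoder_maps, n_fnirs_channels, 2, 2,
                                       rng, dtype)

    # ------------------------------------------------------------------
    def layers(self):
        return [
            self.conv1, self.relu1, self.drop1, self.pool1,
            self.conv2, self.relu2, self.drop2, self.pool2,
            self.lstm1, self.drop3, self.lstm2, self.repeat,
            self.lstm3, self.drop4, self.lstm4, self.drop5,
            self.deconv1, self.relu3, self.drop6, self.deconv2,
        ]

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers())

    def forward(self, X, training=False, rng=None, trace=None):
        N, S, T, C = X.shape
        x = X.reshape(N * S, T, C)
        x = self.pool1.forward(
            self.drop1.forward(
                self.relu1.forward(self.conv1.forward(x)), training, rng
            )
        )
        if trace is not None:
            trace["conv_block1"] = (S,) + x.shape[1:]
        x = self.pool2.forward(
            self.drop2.forward(
                self.relu2.forward(self.conv2.forward(x)), training, rng
            )
        )
        if trace is not None:
            trace["conv_block2"] = (S,) + x.shape[1:]
        self._conv_shape = x.shape
        x = x.reshape(N, S, -1)
        if trace is not None:
            trace["reshape_encoder"] = (S, x.shape[2])
        x = self.drop3.forward(self.lstm1.forward(x), training, rng)
        if trace is not None:
            trace["encoder_lstm1"] = (S, x.shape[2])
        latent = self.lstm2.forward(x)
        if trace is not None:
            trace["latent"] = (1, latent.shape[1])
        x = self.repeat.forward(latent)
        if trace is not None:
            trace["repeat"] = x.shape[1:]
        x = self.drop4.forward(self.lstm3.forward(x), training, rng)
        if trace is not None:
            trace["decoder_lstm3"] = x.shape[1:]
        x = self.drop5.forward(self.lstm4.forward(x), training, rng)
        if trace is not None:
            trace["decoder_lstm4"] = x.shape[1:]
        Sf = self.fnirs_seq_len
        x = x.reshape(N * Sf, self.decoder_base, self.decoder_f3)
        if trace is not None:
            trace["reshape_decoder"] = (Sf, self.decoder_base, self.decoder_f3)
        x = self.drop6.forward(
            self.relu3.forward(self.deconv1.forward(x)), training, rng
        )
        if trace is not None:
            trace["deconv1"] = (Sf,) + x.shape[1:]
        x = self.deconv2.forward(x)
        if trace is not None:
            trace["output"] = (Sf,) + x.shape[1:]
        return x.reshape(N, Sf, self.fnirs_points, self.n_fnirs_channels)

    def backward(self, dY):
        N, Sf = dY.shape[0], dY.shape[1]
        g = dY.reshape(N * Sf, self.fnirs_points, self.n_fnirs_channels)
        g = self.deconv2.backward(g)
        g = self.deconv1.backward(self.relu3.backward(self.drop6.backward(g)))
        g = g.reshape(N, Sf, self.decoder_base * self.decoder_f3)
        g = self.lstm4.backward(self.drop5.backward(g))
        g = self.lstm3.backward(self.drop4.backward(g))
        g = self.lstm2.backward(self.repeat.backward(g))
        g = self.lstm1.backward(self.drop3.backward(g))
        Bc, Lc, Cc = self._conv_shape
        g = g.reshape(Bc, Lc, Cc)
        g = self.conv2.backward(
            self.relu2.backward(self.drop2.backward(self.pool2.backward(g)))
        )
        g = self.conv1.backward(
            self.relu1.backward(self.drop1.backward(self.pool1.backward(g)))
        )
        return g

    def zero_grad(self):
        for l in self.layers():
            l.zero_grad()

    def _clip_scale(self, clip):
        if clip is None or clip <= 0:
            return 1.0
        sq = 0.0
        for l in self.layers():
            for g in l.grads.values():
                sq += float(np.sum(np.square(g, dtype=np.float64)))
        norm = np.sqrt(sq)
        return min(1.0, clip / norm) if norm > 0 else 1.0

    def sgd_step(self, lr, clip):
        step = lr * self._clip_scale(clip)
        for l in self.layers():
            for k in l.params:
                l.params[k] -= (step * l.grads[k]).astype(l.params[k].dtype)

    def adam_step(self, lr, clip, state, betas=(0.9, 0.999), eps=1e-8):
        scale = self._clip_scale(clip)
        b1, b2 = betas
        state["t"] = state.get("t", 0) + 1
        t = state["t"]
        for li, l in enumerate(self.layers()):
            for k in l.params:
                g = l.grads[k] * scale
                key = (li, k)
                if key not in state:
                    state[key] = (np.zeros_like(g), np.zeros_like(g))
                m, v = state[key]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                state[key] = (m, v)
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                l.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(
                    l.params[k].dtype
                )


class CrossModalAutoencoder(BaseEstimator):
    """Predict fNIRS sequence blocks from EEG sequence blocks.

    Parameters
    ----------
    feature_maps : (int, int)
        Feature maps of the two convolutional encoder blocks.
    decoder_maps : int
        Feature maps of the first deconvolution.
    lstm_units : (int, int, int, int)
        Widths of encoder LSTM 1/2 and decoder LSTM 3/4; the second entry
        is the latent width and the fourth must be divisible by
        ``fnirs points per element / 4``.
    activation : {"tanh", "relu"}
        LSTM cell nonlinearity.  "relu" is available but prone to
        divergence with unit-scale initialization; "tanh" is the default.
    init : {"small-uniform", "unit-uniform"}
        Parameter initialization for the LSTMs: U[-0.05, 0.05] with
        forget-gate bias 1, or unit-scale U[0, 1].
    learning_rate, batch_size, epochs, dropout, grad_clip
        Training hyperparameters (defaults 0.05 / 60 / 50 / 0.2 / 1.0).
    optimizer : {"sgd", "adam"}
        Plain SGD via backpropagation through time is the faithful
        default; at desk-scale sample counts it mainly fits the target
        mean, so "adam" is available for experiments where
        input-conditional learning must converge quickly (use a smaller
        learning rate, e.g. 1e-3 - 2e-3).
    random_state : int
        Seed for initialization, the 60/20/20 split and dropout.

    Attributes
    ----------
    net_ : internal layer container
    loss_curve_, val_loss_curve_ : list of float
        Per-epoch training and validation MSE.
    report_ : TrainReport
    n_parameters_ : int
    """

    def __init__(self, feature_maps=(16, 4), decoder_maps=8,
                 lstm_units=(512, 256, 312, 695), conv_kernel=7,
                 conv_stride=2, pool_kernel=2, dropout=0.2,
                 activation="tanh", init="small-uniform",
                 learning_rate=0.05, batch_size=60, epochs=50,
                 grad_clip=1.0, optimizer="sgd", init_scale=0.05,
                 val_fraction=0.2, test_fraction=0.2, random_state=0,
                 dtype="float32", verbose=0):
        self.feature_maps = feature_maps
        self.decoder_maps = decoder_maps
        self.lstm_units = lstm_units
        self.conv_kernel = conv_kernel
        self.conv_stride = conv_stride
        self.pool_kernel = pool_kernel
        self.dropout = dropout
        self.activation = activation
        self.init = init
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.grad_clip = grad_clip
        self.optimizer = optimizer
        self.init_scale = init_scale
        self.val_fraction = val_fraction
        self.test_fraction = test_fraction
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _validate(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError(
                "X must be 4-D (samples, seq_len, points, channels)"
            )
        if y.ndim == 3:
            n, sf, w = y.shape
            # points per element fixed at 20 by the decoder chain
            if w % 20 == 0:
                y = y.reshape(n, sf, 20, w // 20)
            else:
                raise ValueError(
                    "3-D y must have last dim = 20 * n_fnirs_channels"
                )
        if y.ndim != 4:
            raise ValueError("y must be 3-D or 4-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y sample counts differ")
        dt = np.dtype(self.dtype)
        return X.astype(dt, copy=False), y.astype(dt, copy=False)

    def _build(self, X, y, rng):
        n, s, t, c = X.shape
        _, sf, p, cf = y.shape
        return _Net(
            seq_len=s, eeg_points=t, n_eeg_channels=c, fnirs_seq_len=sf,
            fnirs_points=p, n_fnirs_channels=cf,
            feature_maps=self.feature_maps, decoder_maps=self.decoder_maps,
            lstm_units=self.lstm_units, conv_kernel=self.conv_kernel,
            conv_stride=self.conv_stride, pool_kernel=self.pool_kernel,
            dropout=self.dropout, activation=self.activation, init=self.init,
            rng=rng, dtype=np.dtype(self.dtype), init_scale=self.init_scale,
        )

    def fit(self, X, y):
        """Train on sequence pairs, minimizing MSE on the fNIRS blocks."""
        X, y = self._validate(X, y)
        rng = np.random.default_rng(self.random_state)
        t0 = time.time()
        self.net_ = self._build(X, y, rng)
        self.n_parameters_ = self.net_.n_parameters

        n = X.shape[0]
        perm = rng.permutation(n)
        n_test = int(round(self.test_fraction * n))
        n_val = int(round(self.val_fraction * n))
        test_idx = perm[:n_test]
        val_idx = perm[n_test : n_test + n_val]
        train_idx = perm[n_test + n_val :]
        if train_idx.size == 0:
            train_idx = perm
        report = TrainReport(
            train_idx=train_idx, val_idx=val_idx, test_idx=test_idx,
            n_parameters=self.n_parameters_,
        )

        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        opt_state: dict = {}
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            full_batch = self.batch_size >= len(Xtr)
            loss_sum = 0.0
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                # full-batch steps reuse the training tensor itself so the
                # convolutional column cache can take effect
                xb = Xtr if full_batch else Xtr[sel]
                yb = ytr if full_batch else ytr[sel]
                pred = self.net_.forward(xb, training=True, rng=rng)
                resid = pred - yb
                loss = float(np.mean(np.square(resid, dtype=np.float64)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch "
                        f"{epoch + 1}"
                    )
                loss_sum += loss * len(sel)
                self.net_.zero_grad()
                self.net_.backward(
                    (2.0 / resid.size * resid).astype(resid.dtype)
                )
                if self.optimizer == "adam":
                    self.net_.adam_step(
                        self.learning_rate, self.grad_clip, opt_state
                    )
                else:
                    self.net_.sgd_step(self.learning_rate, self.grad_clip)
            report.train_loss.append(loss_sum / len(Xtr))
            if len(Xval):
                vp = self.net_.forward(Xval, training=False)
                vl = float(np.mean(np.square(vp - yval, dtype=np.float64)))
            else:
                vl = report.train_loss[-1]
            report.val_loss.append(vl)
            if self.verbose:
                print(
                    f"epoch {epoch + 1}/{self.epochs} "
                    f"train {report.train_loss[-1]:.5g} val {vl:.5g}"
                )
        report.wall_time_s = time.time() - t0
        self.report_ = report
        self.loss_curve_ = report.train_loss
        self.val_loss_curve_ = report.val_loss
        return self

    def predict(self, X):
        """Reconstruct fNIRS blocks (scaled space); deterministic, dropout off.

        Returns an array of shape (samples, fnirs_seq_len, points,
        n_fnirs_channels).
        """
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.dtype(self.dtype))
        if X.ndim != 4:
            raise ValueError("X must be 4-D")
        return self.net_.forward(X, training=False)

    def score(self, X, y):
        """Negative MSE (higher is better, sklearn convention)."""
        X, y = self._validate(X, y)
        pred = self.predict(X)
        return -float(np.mean(np.square(pred - y, dtype=np.float64)))

    def trace_shapes(self, X):
        """Per-sample output shape of every named stage for input ``X``."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        trace: dict[str, tuple] = {}
        self.net_.forward(
            np.asarray(X[:1], dtype=np.dtype(self.dtype)), trace=trace
        )
        return trace
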