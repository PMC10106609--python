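"""A minimal 1-D convolutional network for the sequence + intensity matrix.

Architecture: one convolution over the one-hot window (position axis, 4
input channels) -> ReLU -> global max pooling -> the intensity feature is
concatenated -> one dense logistic output. Trained full-batch with Adam on
binary cross-entropy; fully deterministic for a fixed seed.

Written in numpy on purpose: the net is tiny (a few thousand parameters)
and a framework dependency would dwarf it.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ConvNet:
    """sklearn-style binary classifier over rows of [4*L one-hot, extras...]."""

    def __init__(self, n_filters: int = 16, kernel: int = 9, epochs: int = 150,
                 lr: float = 0.01, seed: int = 0):
        self.n_filters = n_filters
        self.kernel = kernel
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _split(self, X: np.ndarray):
        L = self._positions
        onehot = X[:, : 4 * L].reshape(-1, L, 4)
        extras = X[:, 4 * L:]
        return onehot, extras

    def _forward(self, windows: np.ndarray, extras: np.ndarray):
        # windows: (n, T, k, 4); conv: (n, T, F)
        conv = np.einsum("ntka,fka->ntf", windows, self.K_) + self.kb_
        relu = np.maximum(conv, 0.0)
        pooled = relu.max(axis=1)  # (n, F)
        argmax = relu.argmax(axis=1)  # (n, F)
        h = np.concatenate([pooled, extras], axis=1)
        z = h @ self.w_ + self.b_
        return conv, argmax, h, z

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        # layout: 4*L one-hot columns, then 0 or 1 continuous extras
        if (d - 1) % 4 == 0:
            L = (d - 1) // 4
        elif d % 4 == 0:
            L = d // 4
        else:
            raise ValueError(f"cannot split {d} columns into one-hot + extras")
        self._positions = L
        rng = np.random.default_rng(self.seed)
        F, k = self.n_filters, self.kernel
        if L < k:
            raise ValueError(f"window of {L} positions shorter than kernel {k}")
        n_extras = d - 4 * L
        self.K_ = rng.normal(0.0, 0.1, size=(F, k, 4))
        self.kb_ = np.zeros(F)
        self.w_ = rng.normal(0.0, 0.1, size=F + n_extras)
        self.b_ = 0.0
        self.classes_ = np.array([0, 1])

        onehot, extras = self._split(X)
        windows = np.lib.stride_tricks.sliding_window_view(
            onehot, (k, 4), axis=(1, 2)
        ).reshape(n, L - k + 1, k, 4)

        # Adam state
        params = ["K_", "kb_", "w_", "b_"]
        m = {p: np.zeros_like(getattr(self, p), dtype=float) for p in params}
        v = {p: np.zeros_like(getattr(self, p), dtype=float) for p in params}
        b1, b2, eps = 0.9, 0.999, 1e-8

        T = windows.shape[1]
        for t in range(1, self.epochs + 1):
            conv, argmax, h, z = self._forward(windows, extras)
            p = _sigmoid(z)
            dz = (p - y) / n  # (n,)
            grads = {
                "w_": h.T @ dz,
                "b_": float(dz.sum()),
            }
            dh = np.outer(dz, self.w_)  # (n, F + extras)
            dpool = dh[:, : self.n_filters]  # (n, F)
            # route pooled gradient back to the argmax time step, through ReLU
            dconv = np.zeros_like(conv)
            ii = np.arange(n)[:, None]
            ff = np.arange(self.n_filters)[None, :]
            dconv[ii, argmax, ff] = dpool * (conv[ii, argmax, ff] > 0)
            grads["K_"] = np.einsum("ntf,ntka->fka", dconv, windows)
            grads["kb_"] = dconv.sum(axis=(0, 1))
            for pname in params:
                g = grads[pname]
                m[pname] = b1 * m[pname] + (1 - b1) * np.asarray(g, dtype=float)
                v[pname] = b2 * v[pname] + (1 - b2) * np.square(g)
                mhat = m[pname] / (1 - b1**t)
                vhat = v[pname] / (1 - b2**t)
                step = self.lr * mhat / (np.sqrt(vhat) + eps)
                if pname == "b_":
                    self.b_ -= float(step)
                else:
                    setattr(self, pname, getattr(self, pname) - step)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        onehot, extras = self._split(X)
        n, L = onehot.shape[0], onehot.shape[1]
        k = self.kernel
        windows = np.lib.stride_tricks.sliding_window_view(
            onehot, (k, 4), axis=(1, 2)
        ).reshape(n, L - k + 1, k, 4)
        _, _, _, z = self._forward(windows, extras)
        p1 = _sigmoid(z)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
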